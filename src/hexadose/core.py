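"""Domain types for karyotype-aware allohexaploid transcriptome analysis.

The hexaploid wheat genome (AABBDD, 2n = 6x = 42) is modelled as 21
chromosomes named ``1A`` .. ``7D`` plus the pseudo-chromosome ``Un`` for
unplaced scaffolds.  A :class:`Karyotype` maps chromosomes (or intervals
within them) to copy numbers, so aneuploid genotypes such as a 4B
monosomic (one copy instead of the disomic two) or a segmental
tetrasomic (four copies of a chromosome-arm segment) are expressed as
overrides on a baseline copy number of 2.

Coordinates are 0-based half-open internally; GFF3 input/output is
1-based inclusive and BED is 0-based half-open, with conversion at the
I/O boundary (see :mod:`hexadose.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

HOMEOLOGOUS_GROUPS = tuple(range(1, 8))
SUBGENOMES = ("A", "B", "D")
#: The 21 wheat chromosomes in karyotype order.
CHROMOSOMES = tuple(f"{g}{s}" for g in HOMEOLOGOUS_GROUPS for s in SUBGENOMES)
UNPLACED = "Un"

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "length", "subgenome"]


def subgenome_of(chromosome: str) -> str:
    """Subgenome letter implied by a chromosome name; 'unknown' for Un/other."""
    if chromosome in CHROMOSOMES:
        return chromosome[-1]
    return "unknown"


def make_annotation(
    gene_ids: Sequence[str],
    chromosomes: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
) -> pd.DataFrame:
    """Assemble a gene annotation table (the package's coordinate backbone).

    Returns a DataFrame indexed by ``gene_id`` with columns
    ``chromosome, start, end, length, subgenome`` using internal
    0-based half-open coordinates.  Raises ``ValueError`` on non-positive
    lengths or a subgenome/chromosome mismatch (impossible here since the
    subgenome is derived, but lengths are validated).
    """
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object),
            "chromosome": np.asarray(chromosomes, dtype=object),
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
        }
    )
    df["length"] = df["end"] - df["start"]
    if (df["length"] <= 0).any():
        bad = df.loc[df["length"] <= 0, "gene_id"].iloc[0]
        raise ValueError(f"non-positive gene length for {bad!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    df["subgenome"] = df["chromosome"].map(subgenome_of)
    return df.set_index("gene_id", drop=False)


def gene_midpoints(annotation: pd.DataFrame) -> pd.Series:
    """Integer midpoint of each gene interval (the single x-coordinate
    used for chromosome profiles and segment membership)."""
    return (annotation["start"] + annotation["end"]) // 2


@dataclass(frozen=True)
class CopyNumberOverride:
    """Copy-number override for a whole chromosome or an interval on it.

    ``start``/``end`` are 0-based half-open; both ``None`` means the whole
    chromosome.
    """

    chromosome: str
    copy_number: int
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if (self.start is None) != (self.end is None):
            raise ValueError("interval override needs both start and end")
        if self.start is not None and self.end <= self.start:
            raise ValueError("override interval must be non-empty")

    @property
    def whole_chromosome(self) -> bool:
        return self.start is None

    def covers(self, position: int) -> bool:
        if self.whole_chromosome:
            return True
        return self.start <= position < self.end


@dataclass(frozen=True)
class Karyotype:
    """Per-genotype chromosome copy-number map.

    ``baseline_copy`` is 2 for a disomic hexaploid; ``overrides`` encode
    aneuploidy (monosomy 1, trisomy 3, nullisomy 0, segmental tetrasomy 4).
    Overrides on the same chromosome must not overlap.
    """

    genotype_name: str
    baseline_copy: int = 2
    overrides: tuple[CopyNumberOverride, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.baseline_copy < 0:
            raise ValueError("baseline_copy must be >= 0")
        object.__setattr__(self, "overrides", tuple(self.overrides))
        by_chrom: dict[str, list[CopyNumberOverride]] = {}
        for ov in self.overrides:
            by_chrom.setdefault(ov.chromosome, []).append(ov)
        for chrom, ovs in by_chrom.items():
            if len(ovs) > 1:
                if any(o.whole_chromosome for o in ovs):
                    raise ValueError(f"overlapping overrides on {chrom}")
                ivs = sorted((o.start, o.end) for o in ovs)
                for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                    if s2 < e1:
                        raise ValueError(f"overlapping overrides on {chrom}")

    def is_euploid(self) -> bool:
        return not self.overrides and self.baseline_copy == 2

    def varied_chromosomes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(ov.chromosome for ov in self.overrides))


def dosage_of(karyotype: Karyotype, chromosome: str, position: int) -> int:
    """Copy number at a genomic position under a karyotype.

    Interval overrides apply when the position (a gene midpoint by
    convention) falls inside them; otherwise the baseline copy number.
    """
    for ov in karyotype.overrides:
        if ov.chromosome == chromosome and ov.covers(position):
            return ov.copy_number
    return karyotype.baseline_copy


def dosage_vector(karyotype: Karyotype, annotation: pd.DataFrame) -> pd.Series:
    """Per-gene copy number under one karyotype (midpoint rule), vectorized."""
    mids = gene_midpoints(annotation)
    out = np.full(len(annotation), karyotype.baseline_copy, dtype=np.int64)
    chrom = annotation["chromosome"].to_numpy()
    for ov in karyotype.overrides:
        on = chrom == ov.chromosome
        if not ov.whole_chromosome:
            on = on & (mids.to_numpy() >= ov.start) & (mids.to_numpy() < ov.end)
        out[on] = ov.copy_number
    return pd.Series(out, index=annotation.index, name=karyotype.genotype_name)


def dosage_matrix(
    karyotypes: Mapping[str, Karyotype], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Genes x genotypes copy-number matrix."""
    return pd.DataFrame(
        {name: dosage_vector(k, annotation) for name, k in karyotypes.items()}
    )


def make_design(
    samples: Iterable[tuple[str, str, int]] | pd.DataFrame,
) -> pd.DataFrame:
    """Sample design table: columns ``sample, genotype, replicate``.

    Accepts an iterable of (sample_id, genotype, replicate) tuples or an
    equivalently shaped DataFrame.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples.loc[:, ["sample", "genotype", "replicate"]].copy()
    else:
        df = pd.DataFrame(list(samples), columns=["sample", "genotype", "replicate"])
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    df["replicate"] = df["replicate"].astype(int)
    return df.reset_index(drop=True)


def samples_of(design: pd.DataFrame, genotype: str) -> list[str]:
    sel = design.loc[design["genotype"] == genotype, "sample"]
    if sel.empty:
        raise KeyError(f"genotype {genotype!r} not in design")
    return sel.tolist()


def make_triad_catalog(
    records: Iterable[tuple[str, str, str, str]] | pd.DataFrame,
    annotation: Optional[pd.DataFrame] = None,
    syntenic: bool = True,
) -> pd.DataFrame:
    """Triad table: columns ``triad_id, A, B, D, syntenic``.

    A triad is one homeologous gene copy per subgenome.  When an
    annotation is supplied, each member is checked against its expected
    subgenome and membership uniqueness is enforced.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "syntenic" not in df.columns:
            df["syntenic"] = syntenic
        df = df.loc[:, ["triad_id", "A", "B", "D", "syntenic"]]
    else:
        df = pd.DataFrame(list(records), columns=["triad_id", "A", "B", "D"])
        df["syntenic"] = syntenic
    df["syntenic"] = df["syntenic"].astype(bool)
    members = pd.concat([df["A"], df["B"], df["D"]])
    if members.duplicated().any():
        dup = members[members.duplicated()].iloc[0]
        raise ValueError(f"gene {dup!r} belongs to more than one triad")
    if annotation is not None:
        for sub in SUBGENOMES:
            genes = df[sub]
            missing = ~genes.isin(annotation.index)
            if missing.any():
                raise ValueError(f"triad member {genes[missing].iloc[0]!r} not annotated")
            got = annotation.loc[genes, "subgenome"].to_numpy()
            if (got != sub).any():
                bad = genes[got != sub].iloc[0]
                raise ValueError(f"triad member {bad!r} is not on subgenome {sub}")
    return df.reset_index(drop=True)
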