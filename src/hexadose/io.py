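"""Readers and writers for the pipeline's tabular interfaces.

Annotation comes in as GFF3 (1-based inclusive), BED (0-based half-open)
or a plain TSV already in the internal convention; triads, karyotypes,
sample designs and count matrices travel as TSV with a header row.
All readers return the pandas containers defined in :mod:`hexadose.core`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .core import (
    CHROMOSOMES,
    UNPLACED,
    CopyNumberOverride,
    Karyotype,
    make_annotation,
    make_design,
    make_triad_catalog,
    subgenome_of,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _warn_unknown_chromosomes(annotation: pd.DataFrame) -> None:
    unknown = annotation.loc[
        ~annotation["chromosome"].isin(CHROMOSOMES + (UNPLACED,)), "chromosome"
    ].unique()
    for chrom in unknown:
        logger.warning(
            "unknown chromosome label %r: records kept with subgenome=unknown", chrom
        )


def read_annotation(path: PathLike, format: str = "gff3") -> pd.DataFrame:
    """Read a gene annotation file into the internal annotation table.

    ``format`` is one of ``gff3`` (gene features; 1-based inclusive
    coordinates converted to 0-based half-open), ``bed`` (already
    half-open) or ``tsv`` (internal convention, as written by
    :func:`write_annotation_tsv`).  Records on unrecognized chromosomes
    are retained with ``subgenome='unknown'`` and a logged warning.
    """
    path = Path(path)
    if format == "gff3":
        import gffutils

        try:
            db = gffutils.create_db(
                str(path),
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="error",
            )
        except Exception as exc:  # gffutils wraps line-level failures
            raise ValueError(f"malformed GFF3 in {path}: {exc}") from exc
        ids, chroms, starts, ends = [], [], [], []
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            ids.append(gid)
            chroms.append(feat.seqid)
            starts.append(feat.start - 1)  # GFF3 1-based inclusive -> half-open
            ends.append(feat.end)
    elif format == "bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        if bed[["chrom", "start", "end", "name"]].isna().any().any():
            raise ValueError(f"malformed BED record in {path}")
        ids = bed["name"].tolist()
        chroms = bed["chrom"].tolist()
        starts = bed["start"].tolist()
        ends = bed["end"].tolist()
    elif format == "tsv":
        tsv = pd.read_csv(path, sep="\t")
        ids = tsv["gene_id"].tolist()
        chroms = tsv["chromosome"].tolist()
        starts = tsv["start"].tolist()
        ends = tsv["end"].tolist()
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    ann = make_annotation(ids, chroms, starts, ends)
    _warn_unknown_chromosomes(ann)
    return ann


def write_annotation_tsv(annotation: pd.DataFrame, path: PathLike) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_annotation_gff3(annotation: pd.DataFrame, path: PathLike) -> None:
    """Write genes as GFF3 ``gene`` features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\thexadose\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def write_annotation_bed(annotation: pd.DataFrame, path: PathLike) -> None:
    bed = annotation[["chromosome", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "+"
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_triads(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"triad_id": str})
    return make_triad_catalog(df)


def write_triads(triads: pd.DataFrame, path: PathLike) -> None:
    triads.to_csv(path, sep="\t", index=False)


def read_karyotypes(path: PathLike) -> dict[str, Karyotype]:
    """Read a karyotype TSV (columns ``genotype, chromosome, start, end,
    copies``; empty chromosome row sets the genotype's baseline, empty
    start/end means the whole chromosome)."""
    df = pd.read_csv(path, sep="\t")
    karyotypes: dict[str, Karyotype] = {}
    for genotype, grp in df.groupby("genotype", sort=False):
        baseline = 2
        overrides = []
        for row in grp.itertuples(index=False):
            chrom = row.chromosome
            if pd.isna(chrom) or chrom == "":
                baseline = int(row.copies)
                continue
            if pd.isna(row.start) or pd.isna(row.end):
                overrides.append(CopyNumberOverride(str(chrom), int(row.copies)))
            else:
                overrides.append(
                    CopyNumberOverride(
                        str(chrom), int(row.copies), int(row.start), int(row.end)
                    )
                )
        karyotypes[str(genotype)] = Karyotype(str(genotype), baseline, tuple(overrides))
    return karyotypes


def write_karyotypes(karyotypes: Mapping[str, Karyotype], path: PathLike) -> None:
    rows = []
    for name, k in karyotypes.items():
        if k.baseline_copy != 2:
            rows.append((name, "", "", "", k.baseline_copy))
        for ov in k.overrides:
            rows.append(
                (
                    name,
                    ov.chromosome,
                    "" if ov.start is None else ov.start,
                    "" if ov.end is None else ov.end,
                    ov.copy_number,
                )
            )
        if k.baseline_copy == 2 and not k.overrides:
            rows.append((name, "", "", "", 2))
    pd.DataFrame(
        rows, columns=["genotype", "chromosome", "start", "end", "copies"]
    ).to_csv(path, sep="\t", index=False)


def read_design(path: PathLike) -> pd.DataFrame:
    return make_design(pd.read_csv(path, sep="\t", dtype={"sample": str, "genotype": str}))


def write_design(design: pd.DataFrame, path: PathLike) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_counts(path: PathLike) -> pd.DataFrame:
    """Genes x samples integer count matrix from TSV (first column gene_id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return counts


def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
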