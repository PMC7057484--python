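"""Karyotype-aware synthetic allohexaploid RNA-seq count simulator.

Emulates the design of an aneuploidy transcriptome study on a nascent
hexaploid (AABBDD) wheat line: 21 chromosomes carrying genes organised
partly into A/B/D homeologous triads, and a panel of sibling genotypes
whose karyotypes differ by whole-chromosome or segmental copy-number
changes — monosomy (1 copy), trisomy (3), nullisomy (0) and segmental
tetrasomy (4 copies of a chromosome-arm segment) against the disomic
euploid baseline.

The expression model is deliberately simple and fully known:

* each gene has a euploid expected count ``base`` drawn log-normally;
* a *dosage-responding* gene's expected count scales proportionally
  with its copy number, ``base * dosage / 2``; non-responders ignore
  dosage;
* optionally, the two sister homeoalleles of a cis-affected triad
  member are actively re-scaled so that at ``compensation = 1`` the
  triad's expected total is restored to its euploid value
  (``compensation = 0`` is purely passive buffering);
* optionally, a fraction of genes *off* the varied chromosome receive a
  multiplicative trans-effect in aneuploid genotypes;
* observed counts are negative-binomial with variance
  ``mu + dispersion * mu**2`` around ``library_factor * expected``.

Every stochastic choice flows from a single seeded
``numpy.random.Generator``, so a config + seed pair reproduces the
dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .core import (
    CHROMOSOMES,
    HOMEOLOGOUS_GROUPS,
    SUBGENOMES,
    CopyNumberOverride,
    Karyotype,
    dosage_vector,
    gene_midpoints,
    make_annotation,
    make_design,
    make_triad_catalog,
)

#: Wheat-scale chromosome length used for synthetic coordinates (bp).
DEFAULT_CHROMOSOME_LENGTH = 600_000_000


def default_karyotypes(
    chromosome_length: int = DEFAULT_CHROMOSOME_LENGTH,
    segment_fraction: float = 0.3,
) -> dict[str, Karyotype]:
    """The five study karyotypes.

    ``euploid`` (all chromosomes x2), ``M4B`` (4B monosomic), ``Tri4B``
    (4B trisomic), ``SegT2A`` (a 2A short-arm segment at 4 copies) and
    ``N7B+SegT2A`` (7B nullisomic plus the same 2A segment).  The 2AS
    segment is modelled as the first ``segment_fraction`` of chromosome
    2A.
    """
    seg_end = int(segment_fraction * chromosome_length)
    seg = CopyNumberOverride("2A", 4, 0, seg_end)
    return {
        "euploid": Karyotype("euploid"),
        "M4B": Karyotype("M4B", overrides=(CopyNumberOverride("4B", 1),)),
        "Tri4B": Karyotype("Tri4B", overrides=(CopyNumberOverride("4B", 3),)),
        "SegT2A": Karyotype("SegT2A", overrides=(seg,)),
        "N7B+SegT2A": Karyotype(
            "N7B+SegT2A", overrides=(CopyNumberOverride("7B", 0), seg)
        ),
    }


def expected_mean(base_mean: float, dosage: int, responding: bool) -> float:
    """Expected count of a gene before compensation and trans-effects.

    A responding gene scales proportionally with copy number relative to
    the disomic state (3 copies -> x1.5, 1 copy -> x0.5, 0 -> silenced);
    a non-responding gene stays at its euploid mean.
    """
    if base_mean < 0:
        raise ValueError("base_mean must be >= 0")
    return base_mean * (dosage / 2.0) if responding else base_mean


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    ``genes_per_chromosome`` may be one integer for all 21 chromosomes or
    a per-chromosome mapping (missing chromosomes fall back to the
    mapping's ``"default"`` entry).  ``responding_counts`` pins the exact
    number of dosage-responding genes on named chromosomes; elsewhere
    responders are Bernoulli(``responding_fraction``).  Laws are
    (mean-log, sd-log) pairs of log-normal distributions.
    """

    genes_per_chromosome: Union[int, Mapping[str, int]] = 200
    chromosome_length: int = DEFAULT_CHROMOSOME_LENGTH
    triad_fraction: float = 0.5
    triad_member_sd_log: float = 0.25
    responding_fraction: float = 0.85
    responding_counts: Optional[Mapping[str, int]] = None
    base_mean_law: tuple[float, float] = (5.0, 1.5)
    gene_length_law: tuple[float, float] = (7.6, 0.45)
    dispersion: float = 0.05
    dispersion_sd_log: float = 0.0
    replicates_per_genotype: int = 4
    library_size_sd_log: float = 0.15
    trans_effect_fraction: float = 0.0
    trans_effect_law: tuple[float, float] = (-0.2, 0.1)
    compensation: float = 0.0
    seed: int = 0

    def n_genes(self, chromosome: str) -> int:
        if isinstance(self.genes_per_chromosome, Mapping):
            g = self.genes_per_chromosome
            if chromosome in g:
                return int(g[chromosome])
            if "default" in g:
                return int(g["default"])
            raise KeyError(
                f"genes_per_chromosome has no entry (and no 'default') for {chromosome}"
            )
        return int(self.genes_per_chromosome)

    def validate(self) -> None:
        for name in ("triad_fraction", "responding_fraction", "trans_effect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.compensation <= 1.0:
            raise ValueError("compensation must be in [0, 1]")
        if self.dispersion < 0 or self.dispersion_sd_log < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.replicates_per_genotype < 1:
            raise ValueError("replicates_per_genotype must be >= 1")
        if self.library_size_sd_log < 0 or self.triad_member_sd_log < 0:
            raise ValueError("log-sd parameters must be >= 0")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be > 0")
        for chrom in CHROMOSOMES:
            if self.n_genes(chrom) < 1:
                raise ValueError(f"need >= 1 gene on {chrom}")
        if self.responding_counts is not None:
            for chrom, k in self.responding_counts.items():
                if not 0 <= int(k) <= self.n_genes(chrom):
                    raise ValueError(
                        f"responding_counts[{chrom!r}]={k} outside [0, n_genes]"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["genes_per_chromosome"], Mapping):
            d["genes_per_chromosome"] = dict(d["genes_per_chromosome"])
        if d["responding_counts"] is not None:
            d["responding_counts"] = dict(d["responding_counts"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for law in ("base_mean_law", "gene_length_law", "trans_effect_law"):
            if law in kwargs and kwargs[law] is not None:
                kwargs[law] = tuple(kwargs[law])
        return cls(**kwargs)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`.

    ``truth`` records, per gene, the responding flag, base mean, triad
    membership, and the dosage, expected mean and trans-multiplier under
    each genotype — everything a downstream test needs to score recovery.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    triads: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame
    karyotypes: dict[str, Karyotype]
    config: SimulationConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        from . import io as hio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_counts(self.counts, outdir / "counts.tsv")
        hio.write_annotation_gff3(self.annotation, outdir / "annotation.gff3")
        hio.write_triads(self.triads, outdir / "triads.tsv")
        hio.write_design(self.design, outdir / "design.tsv")
        hio.write_karyotypes(self.karyotypes, outdir / "karyotypes.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _draw_genes(config: SimulationConfig, rng: np.random.Generator):
    ids, chroms, starts, ends = [], [], [], []
    for chrom in CHROMOSOMES:
        n = config.n_genes(chrom)
        lengths = np.maximum(
            rng.lognormal(*config.gene_length_law, size=n).astype(np.int64), 150
        )
        max_start = max(config.chromosome_length - int(lengths.max()) - 1, 1)
        start = np.sort(rng.integers(0, max_start, size=n))
        ids.extend(f"g{chrom}_{i:05d}" for i in range(n))
        chroms.extend([chrom] * n)
        starts.extend(start.tolist())
        ends.extend((start + lengths).tolist())
    return make_annotation(ids, chroms, starts, ends)


def _assign_triads(config, annotation, rng):
    """Pair genes of matching rank across the three subgenome chromosomes
    of each homeologous group into triads."""
    records = []
    triad_of = pd.Series("", index=annotation.index, dtype=object)
    for g in HOMEOLOGOUS_GROUPS:
        ns = [config.n_genes(f"{g}{s}") for s in SUBGENOMES]
        n_triads = int(round(config.triad_fraction * min(ns)))
        if n_triads == 0:
            continue
        picks = {}
        for s, n in zip(SUBGENOMES, ns):
            chosen = np.sort(rng.choice(n, size=n_triads, replace=False))
            genes = annotation.index[annotation["chromosome"] == f"{g}{s}"]
            picks[s] = genes[chosen]
        for t in range(n_triads):
            tid = f"T{g}_{t:05d}"
            members = tuple(picks[s][t] for s in SUBGENOMES)
            records.append((tid, *members))
            for m in members:
                triad_of[m] = tid
    triads = make_triad_catalog(records, annotation)
    return triads, triad_of


def _responding_flags(config, annotation, rng) -> pd.Series:
    flags = np.zeros(len(annotation), dtype=bool)
    chrom = annotation["chromosome"].to_numpy()
    counts = config.responding_counts or {}
    for c in CHROMOSOMES:
        on = np.flatnonzero(chrom == c)
        if c in counts:
            chosen = rng.choice(len(on), size=int(counts[c]), replace=False)
            flags[on[chosen]] = True
        else:
            flags[on] = rng.random(len(on)) < config.responding_fraction
    return pd.Series(flags, index=annotation.index)


def _compensate(
    means: np.ndarray,
    base: np.ndarray,
    dosage: np.ndarray,
    responding: np.ndarray,
    triad_groups: list[np.ndarray],
    compensation: float,
) -> np.ndarray:
    """Scale the unaffected sisters of cis-affected triad members so that
    at compensation=1 each triad's expected total equals its euploid total."""
    out = means.copy()
    for members in triad_groups:
        d = dosage[members]
        affected = responding[members] & (d != 2)
        if not affected.any():
            continue
        sisters = members[d == 2]
        sister_sum = base[sisters].sum()
        if sister_sum <= 0 or len(sisters) == 0:
            continue
        deficit = (base[members][affected] * (1.0 - d[affected] / 2.0)).sum()
        factor = max(1.0 + compensation * deficit / sister_sum, 0.0)
        out[sisters] = out[sisters] * factor
    return out


def simulate_dataset(
    config: SimulationConfig,
    karyotypes: Optional[Mapping[str, Karyotype]] = None,
) -> SimulatedDataset:
    """Simulate a full genes x samples count dataset with known truth.

    ``karyotypes`` defaults to the five study genotypes
    (:func:`default_karyotypes`); one of them must be named ``euploid``.
    """
    config.validate()
    if karyotypes is None:
        karyotypes = default_karyotypes(config.chromosome_length)
    karyotypes = dict(karyotypes)
    if "euploid" not in karyotypes:
        raise ValueError("karyotype set must include a genotype named 'euploid'")

    rng = np.random.default_rng(config.seed)
    annotation = _draw_genes(config, rng)
    n = len(annotation)
    triads, triad_of = _assign_triads(config, annotation, rng)
    responding = _responding_flags(config, annotation, rng)

    # base means: triad members share a triad-level base times member jitter
    base = rng.lognormal(*config.base_mean_law, size=n)
    if len(triads):
        member_cols = triads[list(SUBGENOMES)].to_numpy()
        triad_base = rng.lognormal(*config.base_mean_law, size=len(triads))
        jitter = (
            rng.lognormal(0.0, config.triad_member_sd_log, size=member_cols.shape)
            if config.triad_member_sd_log > 0
            else np.ones(member_cols.shape)
        )
        pos = pd.Series(np.arange(n), index=annotation.index)
        for j in range(3):
            base[pos[member_cols[:, j]].to_numpy()] = triad_base * jitter[:, j]

    trans_flag = rng.random(n) < config.trans_effect_fraction
    if config.dispersion_sd_log > 0:
        alpha = config.dispersion * rng.lognormal(0.0, config.dispersion_sd_log, size=n)
    else:
        alpha = np.full(n, config.dispersion)

    triad_groups = []
    if len(triads):
        pos = pd.Series(np.arange(n), index=annotation.index)
        for row in triads.itertuples(index=False):
            triad_groups.append(pos[[row.A, row.B, row.D]].to_numpy())

    genotype_names = list(karyotypes)
    design = make_design(
        (f"{g}_r{j + 1}", g, j + 1)
        for g in genotype_names
        for j in range(config.replicates_per_genotype)
    )

    resp_arr = responding.to_numpy()
    expected: dict[str, np.ndarray] = {}
    trans_mult: dict[str, np.ndarray] = {}
    dosages: dict[str, np.ndarray] = {}
    for g in genotype_names:
        d = dosage_vector(karyotypes[g], annotation).to_numpy()
        dosages[g] = d
        m = np.where(resp_arr, base * d / 2.0, base)
        if config.compensation > 0 and triad_groups:
            m = _compensate(m, base, d, resp_arr, triad_groups, config.compensation)
        tm = np.ones(n)
        if config.trans_effect_fraction > 0 and karyotypes[g].overrides:
            draw = rng.lognormal(*config.trans_effect_law, size=n)
            on = trans_flag & (d == karyotypes[g].baseline_copy)
            tm[on] = draw[on]
        trans_mult[g] = tm
        expected[g] = m * tm

    lib = rng.lognormal(0.0, config.library_size_sd_log, size=len(design))
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, row in enumerate(design.itertuples(index=False)):
        mu = lib[j] * expected[row.genotype]
        counts[:, j] = _nb_draw(rng, mu, alpha)
    counts_df = pd.DataFrame(counts, index=annotation.index, columns=design["sample"])

    truth = annotation[["gene_id", "chromosome", "length"]].copy()
    truth["position"] = gene_midpoints(annotation)
    truth["base_mean"] = base
    truth["responding"] = resp_arr
    truth["trans_effect"] = trans_flag
    truth["triad_id"] = triad_of
    for g in genotype_names:
        truth[f"dosage_{g}"] = dosages[g]
        truth[f"expected_mean_{g}"] = expected[g]
        truth[f"trans_mult_{g}"] = trans_mult[g]

    return SimulatedDataset(
        counts=counts_df,
        annotation=annotation,
        triads=triads,
        design=design,
        truth=truth.reset_index(drop=True),
        karyotypes=karyotypes,
        config=config,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance = mu + alpha mu^2) sampler; alpha == 0 is Poisson."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois & (mu > 0)
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out
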