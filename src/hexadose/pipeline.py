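"""End-to-end pipeline: simulate or load data, then run every stage.

A :class:`PipelineConfig` (usually from a YAML file) names the inputs
(or a ``simulate`` block), the aneuploid-vs-euploid contrasts, and the
thresholds (FPKM filter 1, FDR 0.05, loess span 0.1).  ``run_pipeline``
executes quantification, chromosome ratio profiling, dosage-correlation
testing, NB differential expression and the triad buffering analysis in
dependency order, writing machine-diffable TSV tables and a run log that
records gene counts at every filter boundary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as hio
from .core import Karyotype
from .core import dosage_of as _dosage_at
from .de import dtg_chromosome_table, estimate_dispersion, nb_wald_test, size_factors
from .dosage import dosage_correlated_fraction, dosage_correlation_test
from .profiling import log2_ratio_profile, region_summary, smooth_profile
from .quantify import compute_fpkm, filter_expressed, replicate_correlation
from .simulate import SimulationConfig, default_karyotypes, simulate_dataset
from .triads import buffering_report, classify_bias, dtt_test, triad_expression

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    outdir: str = "hexadose_out"
    seed: int = 0
    euploid: str = "euploid"
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("M4B", "euploid"),
            ("Tri4B", "euploid"),
            ("SegT2A", "euploid"),
            ("N7B+SegT2A", "SegT2A"),
        ]
    )
    fpkm_filter: float = 1.0
    fdr: float = 0.05
    loess_span: float = 0.1
    simulate: Optional[SimulationConfig] = None
    counts: Optional[str] = None
    annotation: Optional[str] = None
    annotation_format: str = "gff3"
    triads: Optional[str] = None
    karyotypes: Optional[str] = None
    design: Optional[str] = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "seed" not in sim:
                sim = {**sim, "seed": cfg.seed}
            cfg.simulate = SimulationConfig.from_dict(sim)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["contrasts"] = [list(c) for c in self.contrasts]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def validate(self) -> None:
        if self.fpkm_filter <= 0 or self.fdr <= 0 or not 0 < self.loess_span <= 1:
            raise ValueError("thresholds must be positive (loess span in (0,1])")
        if self.simulate is None:
            needed = ("counts", "annotation", "triads", "karyotypes", "design")
            missing = [n for n in needed if getattr(self, n) is None]
            if missing:
                raise ValueError(
                    f"either a simulate block or input paths are required; "
                    f"missing {missing}"
                )
        else:
            self.simulate.validate()


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        data = simulate_dataset(config.simulate)
        return (
            data.counts,
            data.annotation,
            data.triads,
            data.karyotypes,
            data.design,
            data,
        )
    counts = hio.read_counts(config.counts)
    annotation = hio.read_annotation(config.annotation, config.annotation_format)
    triads = hio.read_triads(config.triads)
    karyotypes = hio.read_karyotypes(config.karyotypes)
    design = hio.read_design(config.design)
    return counts, annotation, triads, karyotypes, design, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    counts, annotation, triads, karyotypes, design, data = _load_inputs(config)
    genotypes = sorted(design["genotype"].unique())
    if config.euploid not in genotypes:
        raise ValueError(f"euploid genotype {config.euploid!r} absent from design")
    for a, e in config.contrasts:
        for g in (a, e):
            if g not in genotypes:
                raise ValueError(f"contrast genotype {g!r} absent from design")
    if data is not None:
        data.write(outdir / "simulated")
        log(f"simulate: {len(counts)} genes x {counts.shape[1]} samples")
    log(f"input: {len(counts)} genes, {counts.shape[1]} samples, "
        f"{len(triads)} triads, genotypes={genotypes}")

    # --- quantification -------------------------------------------------
    fpkm = compute_fpkm(counts, annotation["length"], design)
    fpkm.samples.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id")
    fpkm.by_genotype.to_csv(
        outdir / "fpkm_by_genotype.tsv", sep="\t", index_label="gene_id"
    )
    qc = replicate_correlation(fpkm)
    qc.to_csv(outdir / "replicate_qc.tsv", sep="\t", index=False)
    expressed = filter_expressed(fpkm, config.fpkm_filter)
    log(
        f"quantify: FPKM>{config.fpkm_filter} filter kept {len(expressed)} genes, "
        f"dropped {len(counts) - len(expressed)} (kept + dropped = {len(counts)})"
    )

    # --- profiles and region summaries ---------------------------------
    summaries = []
    for aneu, eu in config.contrasts:
        profile = log2_ratio_profile(fpkm, annotation, aneu, eu, genes=expressed)
        smoothed = smooth_profile(profile, span=config.loess_span)
        tag = f"{aneu}_vs_{eu}".replace("+", "")
        profile.to_csv(outdir / f"ratios_{tag}.tsv", sep="\t", index=False)
        smoothed.to_csv(outdir / f"smoothed_{tag}.tsv", sep="\t", index=False)
        log(f"profile {aneu} vs {eu}: {len(profile)} genes with finite ratios")
        for chrom in karyotypes[aneu].varied_chromosomes():
            try:
                s = region_summary(profile, chrom)
            except ValueError:
                continue
            s["contrast"] = f"{aneu}_vs_{eu}"
            summaries.append(s)
        if config.plots:
            _plot_profile(smoothed, outdir / f"profile_{tag}.png")
    if summaries:
        pd.DataFrame(summaries).to_csv(
            outdir / "region_summaries.tsv", sep="\t", index=False
        )

    # --- dosage correlation ---------------------------------------------
    dosage_genotypes = sorted(
        {config.euploid}
        | {g for pair in config.contrasts for g in pair if g in genotypes}
    )
    dtest = dosage_correlation_test(
        fpkm, annotation, karyotypes, dosage_genotypes, genes=expressed
    )
    dtest.to_csv(outdir / "dosage_test.tsv", sep="\t", index=False)
    n_testable = int(dtest["testable"].sum())
    log(
        f"dosage-test: {n_testable} testable genes of {len(dtest)} "
        f"(untestable + testable = total)"
    )
    frac_rows = []
    for chrom in sorted({c for k in karyotypes.values() for c in k.varied_chromosomes()}):
        try:
            n, frac = dosage_correlated_fraction(
                dtest, annotation, chrom, alpha=config.fdr
            )
        except ValueError:
            continue
        frac_rows.append(
            {"chromosome": chrom, "n_positive": n, "fraction": frac}
        )
    if frac_rows:
        pd.DataFrame(frac_rows).to_csv(
            outdir / "dosage_correlated_fractions.tsv", sep="\t", index=False
        )

    # --- differential expression ----------------------------------------
    factors = size_factors(counts)
    de_by_contrast = {}
    dtg_tables = []
    for aneu, eu in config.contrasts:
        de = nb_wald_test(
            counts, design, aneu, eu, alpha_fdr=config.fdr, genes=expressed,
            factors=factors,
        )
        tag = f"{aneu}_vs_{eu}".replace("+", "")
        de.to_csv(outdir / f"de_{tag}.tsv", sep="\t", index=False)
        de_by_contrast[(aneu, eu)] = de
        dtg_tables.append(dtg_chromosome_table(de, annotation, f"{aneu}_vs_{eu}"))
        log(
            f"de {aneu} vs {eu}: {int(de['tested'].sum())} tested, "
            f"{int(de['dtg_flag'].sum())} DTGs at FDR<{config.fdr}"
        )
    pd.concat(dtg_tables).to_csv(
        outdir / "dtg_by_chromosome.tsv", sep="\t", index_label="direction"
    )

    # --- triads -----------------------------------------------------------
    expr = triad_expression(fpkm, triads, euploid=config.euploid)
    expr.totals_genotype.to_csv(
        outdir / "triads_expr.tsv", sep="\t", index_label="triad_id"
    )
    log(
        f"triads: {int(expr.expressed.sum())} expressed of {len(triads)} "
        f"(summed euploid FPKM > {config.fpkm_filter})"
    )
    expressed_tids = expr.expressed.index[expr.expressed]
    classes = classify_bias(expr.contributions[config.euploid].loc[expressed_tids])
    tern = expr.contributions[config.euploid].loc[expressed_tids].join(classes)
    tern.to_csv(outdir / "triad_class.tsv", sep="\t", index_label="triad_id")

    buffering_rows = []
    for aneu, eu in config.contrasts:
        dtt = dtt_test(expr, [aneu, eu], alpha_fdr=config.fdr)
        tag = f"{aneu}_vs_{eu}".replace("+", "")
        dtt.to_csv(outdir / f"dtt_{tag}.tsv", sep="\t", index=False)
        # regions whose copy number actually differs between the two genotypes
        varied = []
        for ov in karyotypes[aneu].overrides + karyotypes[eu].overrides:
            probe = ov.start if ov.start is not None else 0
            da = _dosage_at(karyotypes[aneu], ov.chromosome, probe)
            de_ = _dosage_at(karyotypes[eu], ov.chromosome, probe)
            if da != de_ and ov not in varied:
                varied.append(ov)
        for ov in varied:
            sub = ov.chromosome[-1] if ov.chromosome[-1] in "ABD" else None
            if sub is None:
                continue
            try:
                rep = buffering_report(
                    expr,
                    de_by_contrast[(aneu, eu)],
                    dtt,
                    annotation,
                    ov.chromosome,
                    sub,
                    f"{aneu}_vs_{eu}",
                    euploid=config.euploid,
                    region=None if ov.whole_chromosome else (ov.start, ov.end),
                )
            except ValueError:
                continue
            cross = rep.pop("category_dtt_crosstab")
            cross.to_csv(
                outdir / f"category_dtt_{tag}_{ov.chromosome}.tsv", sep="\t"
            )
            buffering_rows.append(rep)
            log(
                f"buffering {aneu} vs {eu} on {ov.chromosome}: "
                f"{rep['n_member_dtg']}/{rep['n_expressed_triads']} member DTGs, "
                f"{rep['n_dtt']} DTTs"
            )
    if buffering_rows:
        pd.DataFrame(buffering_rows).to_csv(
            outdir / "buffering_summary.tsv", sep="\t", index=False
        )

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir


def _plot_profile(smoothed: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(smoothed["chromosome"]))
    ncol = 3
    nrow = (len(chroms) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.2 * nrow), squeeze=False)
    for ax, chrom in zip(axes.flat, chroms):
        grp = smoothed[smoothed["chromosome"] == chrom]
        ax.scatter(grp["position"], grp["log2_ratio"], s=2, alpha=0.3)
        ax.plot(grp["position"], grp["smoothed"], lw=1.5, color="crimson")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(chrom, fontsize=8)
    for ax in axes.flat[len(chroms):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
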