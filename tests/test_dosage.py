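"""Per-gene Pearson dosage-correlation tests and region fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexadose import (
    CopyNumberOverride,
    Karyotype,
    SimulationConfig,
    compute_fpkm,
    dosage_correlated_fraction,
    dosage_correlation_test,
    filter_expressed,
    simulate_dataset,
)
from hexadose.core import make_annotation, make_design
from hexadose.quantify import FpkmMatrix, average_by_genotype


def _panel(fpkm_rows, genes_chrom="4B"):
    """One-replicate panel across monosomic/euploid/trisomic genotypes."""
    design = make_design([("m_r1", "m", 1), ("e_r1", "e", 1), ("t_r1", "t", 1)])
    genes = [f"g{i}" for i in range(len(fpkm_rows))]
    samples = pd.DataFrame(
        fpkm_rows, index=genes, columns=["m_r1", "e_r1", "t_r1"]
    ).astype(float)
    fp = FpkmMatrix(samples, average_by_genotype(samples, design), design)
    ann = make_annotation(genes, [genes_chrom] * len(genes), [0] * len(genes),
                          [100] * len(genes))
    kary = {
        "m": Karyotype("m", overrides=(CopyNumberOverride("4B", 1),)),
        "e": Karyotype("e"),
        "t": Karyotype("t", overrides=(CopyNumberOverride("4B", 3),)),
    }
    return fp, ann, kary


def test_pearson_r_and_p_match_formula_oracle():
    """Dosages [1,2,3] and FPKM [10,19,32]: r and the two-sided t-based p
    reproduce the closed-form computation (and scipy's)."""
    fp, ann, kary = _panel([[10, 19, 32]])
    rec = dosage_correlation_test(fp, ann, kary, ["m", "e", "t"])
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([10.0, 19.0, 32.0])
    r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    t_oracle = r_oracle * np.sqrt(1 / (1 - r_oracle**2))  # df = n-2 = 1
    p_oracle = 2 * stats.t.sf(abs(t_oracle), df=1)
    assert rec["r"].iloc[0] == pytest.approx(r_oracle)
    assert rec["p"].iloc[0] == pytest.approx(p_oracle)
    r_sp, p_sp = stats.pearsonr(x, y)
    assert rec["r"].iloc[0] == pytest.approx(r_sp)
    assert rec["p"].iloc[0] == pytest.approx(p_sp)


def test_proportional_fpkm_gives_perfect_correlation():
    design = make_design(
        [(f"{g}_r{j}", g, j) for g in ("m", "e", "t") for j in (1, 2, 3)]
    )
    genes = ["g0"]
    dose = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3], dtype=float)
    samples = pd.DataFrame([10 * dose], index=genes, columns=design["sample"])
    fp = FpkmMatrix(samples, average_by_genotype(samples, design), design)
    ann = make_annotation(genes, ["4B"], [0], [100])
    kary = {
        "m": Karyotype("m", overrides=(CopyNumberOverride("4B", 1),)),
        "e": Karyotype("e"),
        "t": Karyotype("t", overrides=(CopyNumberOverride("4B", 3),)),
    }
    rec = dosage_correlation_test(fp, ann, kary, ["m", "e", "t"])
    assert rec["r"].iloc[0] == pytest.approx(1.0)
    assert rec["p"].iloc[0] < 0.05
    assert rec["n_units"].iloc[0] == 9


def test_constant_fpkm_or_constant_dosage_untestable():
    fp, ann, kary = _panel([[7, 7, 7], [1, 2, 3]])
    rec = dosage_correlation_test(fp, ann, kary, ["m", "e", "t"])
    assert not rec["testable"].iloc[0]
    assert np.isnan(rec["r"].iloc[0])
    # BH ran over the single testable gene only
    assert rec["padj"].iloc[1] == pytest.approx(rec["p"].iloc[1])

    fp2, ann2, kary2 = _panel([[5, 8, 9]], genes_chrom="5A")  # dosage constant
    rec2 = dosage_correlation_test(fp2, ann2, kary2, ["m", "e", "t"])
    assert not rec2["testable"].iloc[0]


def test_fraction_counts_positive_significant_genes():
    records = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "chromosome": ["4B"] * 4,
            "r": [0.9, 0.8, 0.7, 0.6],
            "p": [0.001, 0.15, 0.01, 0.02],
            "padj": [0.01, 0.2, 0.03, 0.04],
            "n_units": 9,
            "dosages": "1,2,3",
            "testable": True,
        }
    ).set_index("gene_id", drop=False)
    ann = make_annotation(list("abcd"), ["4B"] * 4, [0] * 4, [100] * 4)
    n, frac = dosage_correlated_fraction(records, ann, "4B")
    assert (n, frac) == (3, 0.75)
    with pytest.raises(ValueError):
        dosage_correlated_fraction(records, ann, "1A")


def test_null_simulation_controls_fdr():
    """With responding_fraction 0 the positively-correlated fraction at
    FDR 0.05 stays at the nominal level (averaged over 20 seeds)."""
    kary = {
        "euploid": Karyotype("euploid"),
        "M4B": Karyotype("M4B", overrides=(CopyNumberOverride("4B", 1),)),
        "Tri4B": Karyotype("Tri4B", overrides=(CopyNumberOverride("4B", 3),)),
    }
    fracs = []
    for seed in range(20):
        cfg = SimulationConfig(
            genes_per_chromosome={"default": 5, "4B": 150},
            responding_fraction=0.0,
            replicates_per_genotype=3,
            seed=100 + seed,
        )
        d = simulate_dataset(cfg, kary)
        fp = compute_fpkm(d.counts, d.annotation["length"], d.design)
        rec = dosage_correlation_test(
            fp, d.annotation, kary, ["M4B", "euploid", "Tri4B"],
            genes=filter_expressed(fp),
        )
        try:
            _, frac = dosage_correlated_fraction(rec, d.annotation, "4B")
        except ValueError:
            frac = 0.0
        fracs.append(frac)
    assert np.mean(fracs) <= 0.05


def test_power_monotone_in_replicates():
    """More replicates detect at least as large a dosage-correlated
    fraction at fixed effect and seed grid."""
    kary = {
        "euploid": Karyotype("euploid"),
        "M4B": Karyotype("M4B", overrides=(CopyNumberOverride("4B", 1),)),
        "Tri4B": Karyotype("Tri4B", overrides=(CopyNumberOverride("4B", 3),)),
    }

    def mean_frac(reps):
        fracs = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                genes_per_chromosome={"default": 5, "4B": 120},
                responding_fraction=1.0,
                dispersion=0.4,
                replicates_per_genotype=reps,
                seed=seed,
            )
            d = simulate_dataset(cfg, kary)
            fp = compute_fpkm(d.counts, d.annotation["length"], d.design)
            rec = dosage_correlation_test(
                fp, d.annotation, kary, ["M4B", "euploid", "Tri4B"],
                genes=filter_expressed(fp),
            )
            fracs.append(dosage_correlated_fraction(rec, d.annotation, "4B")[1])
        return np.mean(fracs)

    assert mean_frac(6) >= mean_frac(2)
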