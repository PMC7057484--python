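"""Negative-binomial Wald test for differential transcription.

A transparent two-group NB pipeline on raw counts:

1. **Size factors** — median-of-ratios: each sample's median ratio of
   counts to the per-gene geometric mean, over genes with nonzero counts
   in every sample.
2. **Dispersion** — per-gene method-of-moments estimates
   ``alpha = (s^2 - m) / m^2`` pooled across replicate groups on
   normalized counts, floored at 1e-8, then shrunk toward a fitted
   mean-dispersion trend ``alpha(mu) = a0 + a1 / mu`` (geometric-mean
   shrinkage with weight 0.5 in log space).
3. **Wald test** — log2 fold change of normalized group means with a
   pseudocount of 1/2, delta-method standard error
   ``SE = (1/ln 2) * sqrt((1/m1 + alpha)/n1 + (1/m2 + alpha)/n2)``,
   two-sided normal p-value, BH adjustment over tested genes.

Genes with zero counts in both groups are untested.  Differentially
transcribed genes (DTGs) are those with BH-adjusted p below ``alpha_fdr``
(default 0.05).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    Uses genes with nonzero counts in all samples as the reference set;
    if none exist, pass ``pseudo_reference=True`` to fall back to genes
    with a positive geometric mean over their nonzero samples.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logg = np.log(mat[all_nonzero])
        ref = logg.mean(axis=1)  # log geometric mean per gene
        factors = np.exp(np.median(logg - ref[:, None], axis=0))
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logg = np.where(mat > 0, np.log(mat), np.nan)
        ref = np.nanmean(logg, axis=1)
        use = np.isfinite(ref)
        if not use.any():
            raise ValueError("no usable genes for size-factor estimation")
        ratios = logg[use] - ref[use, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "rerun with pseudo_reference=True"
        )
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame, factors: Optional[pd.Series] = None
) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: Optional[pd.Series] = None,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion from within-group moments, trend-shrunk.

    Groups are the design's genotypes; only groups with >= 2 replicates
    contribute.  The raw method-of-moments estimate is shrunk toward a
    ``a0 + a1/mu`` trend fitted across genes, with ``trend_weight`` on
    the trend in log space.  Raises if no group has replication.
    """
    norm = normalize_counts(counts, factors)
    groups = [
        norm[g["sample"].tolist()]
        for _, g in design.groupby("genotype", sort=False)
        if len(g) >= 2 and set(g["sample"]) <= set(norm.columns)
    ]
    groups = [g for g in groups if g.shape[1] >= 2]
    if not groups:
        raise ValueError("dispersion estimation needs >= 2 replicates in some group")

    num = np.zeros(len(norm))
    den = np.zeros(len(norm))
    mu_all = np.zeros(len(norm))
    w_all = 0.0
    for g in groups:
        m = g.mean(axis=1).to_numpy()
        v = g.var(axis=1, ddof=1).to_numpy()
        w = g.shape[1] - 1
        ok = m > 0
        num[ok] += w * (v[ok] - m[ok]) / m[ok] ** 2
        den[ok] += w
        mu_all += w * m
        w_all += w
    mu = mu_all / w_all
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    raw = np.where(np.isfinite(raw), raw, DISPERSION_FLOOR)
    raw = np.maximum(raw, DISPERSION_FLOOR)

    trend = _fit_trend(mu, raw)
    shrunk = np.exp(
        (1.0 - trend_weight) * np.log(raw) + trend_weight * np.log(trend)
    )
    return pd.Series(np.maximum(shrunk, DISPERSION_FLOOR), index=counts.index,
                     name="dispersion")


def _fit_trend(mu: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over informative genes (raw above the
    floor, positive mean), nonnegative coefficients; constant fallback."""
    ok = (mu > 0) & (raw > DISPERSION_FLOOR * 10)
    floor_trend = np.full(mu.shape, DISPERSION_FLOOR * 10)
    if ok.sum() < 10:
        med = np.median(raw[ok]) if ok.any() else DISPERSION_FLOOR
        return np.maximum(np.full(mu.shape, med), floor_trend)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    coef = np.maximum(coef, 0.0)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(mu, 1e-12)
    med = np.median(raw[ok])
    trend = np.where(np.isfinite(trend) & (trend > 0), trend, med)
    return np.maximum(trend, floor_trend)


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group1: str,
    group2: str,
    alpha_fdr: float = 0.05,
    genes: Optional[pd.Index] = None,
    factors: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential-transcription test.

    ``group1`` is the numerator genotype of the log2 fold change (so in
    an 'aneuploid vs euploid' contrast pass the aneuploid first).  BH
    adjustment runs over the tested genes (optionally pre-restricted to
    an expression-filtered ``genes`` subset).  Returns columns
    ``gene_id, base_mean, log2_fold_change, lfc_se, stat, p, padj,
    dtg_flag, tested``.
    """
    for g in (group1, group2):
        if not (design["genotype"] == g).any():
            raise KeyError(f"genotype {g!r} not in design")
    if factors is None:
        factors = size_factors(counts)
    if dispersions is None:
        both = design[design["genotype"].isin([group1, group2])]
        dispersions = estimate_dispersion(counts, both, factors)
    norm = normalize_counts(counts, factors)
    if genes is not None:
        norm = norm.loc[norm.index.intersection(genes)]
    disp = dispersions.reindex(norm.index).to_numpy()

    s1 = design.loc[design["genotype"] == group1, "sample"].tolist()
    s2 = design.loc[design["genotype"] == group2, "sample"].tolist()
    m1 = norm[s1].mean(axis=1).to_numpy()
    m2 = norm[s2].mean(axis=1).to_numpy()
    tested = (m1 > 0) | (m2 > 0)

    n1, n2 = len(s1), len(s2)
    lfc = np.log2(m1 + 0.5) - np.log2(m2 + 0.5)
    se = (
        np.sqrt((1.0 / (m1 + 0.5) + disp) / n1 + (1.0 / (m2 + 0.5) + disp) / n2)
        / LN2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    p = np.where(tested, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    padj = bh_adjust(p)

    out = pd.DataFrame(
        {
            "gene_id": norm.index,
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2_fold_change": np.where(tested, lfc, np.nan),
            "lfc_se": np.where(tested, se, np.nan),
            "stat": np.where(tested, stat, np.nan),
            "p": p,
            "padj": padj,
            "dtg_flag": np.where(tested, padj < alpha_fdr, False).astype(bool),
            "tested": tested,
        }
    ).set_index("gene_id", drop=False)
    return out


def dtg_chromosome_table(
    de: pd.DataFrame, annotation: pd.DataFrame, contrast: str
) -> pd.DataFrame:
    """Down/Up DTG counts per chromosome (the Table-2-shaped layout)."""
    ann = annotation.loc[annotation.index.intersection(de.index)]
    dtg = de.loc[ann.index]
    dtg = dtg[dtg["dtg_flag"]]
    chroms = list(dict.fromkeys(annotation["chromosome"]))
    rows = {}
    for direction, sel in (
        ("Down", dtg["log2_fold_change"] < 0),
        ("Up", dtg["log2_fold_change"] > 0),
    ):
        sub = annotation.loc[dtg.index[sel], "chromosome"].value_counts()
        rows[direction] = [int(sub.get(c, 0)) for c in chroms] + [int(sel.sum())]
    table = pd.DataFrame(rows, index=chroms + ["Total"]).T
    table.insert(0, "contrast", contrast)
    return table
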