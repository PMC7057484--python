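"""Homeolog-triad expression, ternary bias classification and buffering.

A triad is one homeologous gene copy per subgenome (A, B, D).  The
triad's transcriptional output is the sum of its members' FPKM; the
relative contribution of each member (a, b, d with a + b + d = 1) places
the triad on a ternary simplex that is classified into seven bias
categories by nearest Euclidean centroid:

* balanced (1/3, 1/3, 1/3)
* A-/B-/D-dominant — (1, 0, 0)-type corners
* A-/B-/D-suppressed — (0, 1/2, 1/2)-type edge midpoints

Buffering is quantified by contrasting per-gene dosage response (DTGs)
with per-triad total-output response (DTTs, one-way ANOVA across
genotypes): when sister homeoalleles absorb a member's dosage change,
triad totals move far less than member genes do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .core import SUBGENOMES
from .quantify import FpkmMatrix, average_by_genotype

#: Category labels in fixed tie-break order.
CATEGORIES = (
    "balanced",
    "A-dominant",
    "B-dominant",
    "D-dominant",
    "A-suppressed",
    "B-suppressed",
    "D-suppressed",
)

CENTROIDS = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.5, 0.5],
        [0.5, 0.0, 0.5],
        [0.5, 0.5, 0.0],
    ]
)


@dataclass
class TriadExpression:
    """Triad-level abundances derived from an FPKM matrix.

    ``totals_samples``: triads x samples summed FPKM;
    ``totals_genotype``: replicate-averaged totals;
    ``contributions``: genotype -> triads x (a, b, d) relative member
    contributions; ``expressed``: summed euploid mean FPKM > 1.
    """

    triads: pd.DataFrame
    totals_samples: pd.DataFrame
    totals_genotype: pd.DataFrame
    contributions: dict[str, pd.DataFrame]
    expressed: pd.Series
    design: pd.DataFrame


def triad_expression(
    fpkm: FpkmMatrix,
    triads: pd.DataFrame,
    euploid: str = "euploid",
    expression_threshold: float = 1.0,
) -> TriadExpression:
    """Summed and relative homeoallele expression per triad.

    Members absent from the FPKM matrix contribute zero (with a
    warning-level log entry left to the caller's discretion).  A triad is
    *expressed* when the summed euploid genotype-mean FPKM exceeds
    ``expression_threshold`` (the 'greater than unity' rule).
    """
    tid = triads["triad_id"]
    member_mats = {}
    for sub in SUBGENOMES:
        genes = triads[sub]
        mat = fpkm.samples.reindex(genes).fillna(0.0)
        mat.index = tid
        member_mats[sub] = mat
    totals_samples = sum(member_mats.values())
    totals_genotype = average_by_genotype(totals_samples, fpkm.design)

    member_geno = {
        sub: average_by_genotype(member_mats[sub], fpkm.design) for sub in SUBGENOMES
    }
    contributions = {}
    for g in totals_genotype.columns:
        tot = totals_genotype[g].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.column_stack(
                [member_geno[sub][g].to_numpy() / tot for sub in SUBGENOMES]
            )
        contributions[g] = pd.DataFrame(
            contrib, index=tid, columns=[s.lower() for s in SUBGENOMES]
        )
    if euploid not in totals_genotype.columns:
        raise KeyError(f"euploid genotype {euploid!r} not in design")
    expressed = totals_genotype[euploid] > expression_threshold
    expressed.name = "expressed"
    return TriadExpression(
        triads=triads,
        totals_samples=totals_samples,
        totals_genotype=totals_genotype,
        contributions=contributions,
        expressed=expressed,
        design=fpkm.design,
    )


def classify_bias(contributions: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Nearest-centroid ternary classification of (a, b, d) contributions.

    Accepts one point or an array of points on the unit simplex; returns
    a DataFrame with the winning ``category`` and the Euclidean distance
    to each of the seven centroids.  Ties break in the fixed order
    balanced, A/B/D-dominant, A/B/D-suppressed.
    """
    if isinstance(contributions, pd.DataFrame):
        idx = contributions.index
        pts = contributions.to_numpy(dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(contributions, dtype=float))
        idx = pd.RangeIndex(len(pts))
    if pts.shape[1] != 3:
        raise ValueError("contributions must have three components")
    sums = pts.sum(axis=1)
    valid = np.isfinite(pts).all(axis=1) & (pts >= -1e-9).all(axis=1)
    if not valid.all() or not np.allclose(sums[valid], 1.0, atol=1e-6):
        raise ValueError("contributions must be nonnegative and sum to 1")
    d = np.sqrt(((pts[:, None, :] - CENTROIDS[None, :, :]) ** 2).sum(axis=2))
    winner = d.argmin(axis=1)  # argmin takes the first minimum: fixed tie order
    out = pd.DataFrame(d, index=idx, columns=[f"dist_{c}" for c in CATEGORIES])
    out.insert(0, "category", [CATEGORIES[i] for i in winner])
    return out


def dtt_test(
    expr: TriadExpression,
    genotypes: Sequence[str],
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA on per-replicate triad totals across genotypes.

    Only expressed triads enter the test and the BH adjustment.  Triads
    with zero variance everywhere are untestable (missing p).  Returns
    ``triad_id, f_stat, p, padj, dtt_flag, tested``; a differentially
    transcribed triad (DTT) has ``padj < alpha_fdr``.
    """
    design = expr.design
    groups_samples = []
    for g in genotypes:
        s = design.loc[design["genotype"] == g, "sample"].tolist()
        if len(s) < 2:
            raise ValueError(f"genotype {g!r} needs >= 2 replicates for ANOVA")
        groups_samples.append(s)
    totals = expr.totals_samples.loc[expr.expressed]
    arrays = [totals[s].to_numpy(dtype=float) for s in groups_samples]

    n_triads = len(totals)
    f = np.full(n_triads, np.nan)
    p = np.full(n_triads, np.nan)
    concat = np.concatenate(arrays, axis=1)
    testable = concat.var(axis=1) > 0
    within_var = np.sum(
        [a.var(axis=1, ddof=1) * (a.shape[1] - 1) for a in arrays], axis=0
    )
    testable &= within_var > 0
    if testable.any():
        fs, ps = stats.f_oneway(*[a[testable].T for a in arrays])
        f[testable] = fs
        p[testable] = ps
    out = pd.DataFrame(
        {
            "triad_id": totals.index,
            "f_stat": f,
            "p": p,
            "padj": bh_adjust(p),
            "tested": testable,
        }
    ).set_index("triad_id", drop=False)
    out["dtt_flag"] = (out["padj"] < alpha_fdr).astype(bool)
    return out


def buffering_report(
    expr: TriadExpression,
    de_records: pd.DataFrame,
    dtt_records: pd.DataFrame,
    annotation: pd.DataFrame,
    varied_chromosome: str,
    varied_subgenome: str,
    contrast: str,
    euploid: str = "euploid",
    region: Optional[tuple[int, int]] = None,
) -> dict:
    """Assemble the per-contrast buffering summary.

    Restricts to expressed triads whose varied-subgenome member lies on
    ``varied_chromosome`` (optionally within ``region``), then reports
    member-gene DTG counts, triad DTT counts, the ternary category x DTT
    cross-table (categories from euploid contributions), and the mean
    relative contribution of the varied subgenome among DTTs vs
    non-DTTs.
    """
    triads = expr.triads.set_index("triad_id")
    member = triads[varied_subgenome.upper()]
    ann = annotation.loc[annotation.index.intersection(member)]
    on = ann["chromosome"] == varied_chromosome
    if region is not None:
        mid = (ann["start"] + ann["end"]) // 2
        on = on & (mid >= region[0]) & (mid < region[1])
    member_on = member[member.isin(ann.index[on])]
    tids = member_on.index.intersection(expr.expressed.index[expr.expressed])
    if not len(tids):
        raise ValueError(f"no expressed triads on {varied_chromosome} for {contrast}")

    member_genes = member.loc[tids]
    de_sub = de_records.reindex(member_genes)
    n_dtg = int(de_sub["dtg_flag"].eq(True).sum())
    dtt_sub = dtt_records.reindex(tids)
    dtt_flags = dtt_sub["dtt_flag"].eq(True)
    n_dtt = int(dtt_flags.sum())

    classes = classify_bias(expr.contributions[euploid].loc[tids])
    cross = (
        pd.crosstab(classes["category"], dtt_flags)
        .reindex(index=list(CATEGORIES), fill_value=0)
        .rename(columns={False: "non_DTT", True: "DTT"})
    )
    contrib = expr.contributions[euploid].loc[tids, varied_subgenome.lower()]
    mean_contrib_dtt = float(contrib[dtt_flags.to_numpy()].mean()) if n_dtt else np.nan
    mean_contrib_non = (
        float(contrib[~dtt_flags.to_numpy()].mean()) if n_dtt < len(tids) else np.nan
    )
    return {
        "contrast": contrast,
        "varied_chromosome": varied_chromosome,
        "n_expressed_triads": int(len(tids)),
        "n_member_dtg": n_dtg,
        "frac_member_dtg": n_dtg / len(tids),
        "n_dtt": n_dtt,
        "frac_dtt": n_dtt / len(tids),
        "category_dtt_crosstab": cross,
        "mean_varied_contribution_dtt": mean_contrib_dtt,
        "mean_varied_contribution_non_dtt": mean_contrib_non,
    }
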