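"""Chromosome profiles of log2(aneuploid/euploid) expression ratios.

Each expressed gene contributes one point — its interval midpoint on the
x axis and the log2 ratio of genotype-averaged FPKM on the y axis.  A
tri-cube-weighted local polynomial (loess) smoother tracks the ratio
distribution along the chromosome; on a dosage-responding chromosome the
curve sits near log2(dosage/2): 0.585 for a trisomic, -1 for a
monosomic, 1 inside a four-copy segment.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .core import gene_midpoints
from .quantify import FpkmMatrix

logger = logging.getLogger(__name__)


def log2_ratio_profile(
    fpkm: FpkmMatrix,
    annotation: pd.DataFrame,
    aneuploid: str,
    euploid: str,
    genes: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Per-gene log2(aneuploid/euploid) ratios of genotype-mean FPKM.

    ``genes`` restricts to an expression-filtered subset.  Genes with a
    zero denominator (or zero numerator, e.g. under nullisomy) have no
    finite ratio; they are excluded and the exclusion count is logged.
    Returns columns ``gene_id, chromosome, position, log2_ratio,
    contrast`` sorted by chromosome and position.
    """
    for g in (aneuploid, euploid):
        if g not in fpkm.by_genotype.columns:
            raise KeyError(f"genotype {g!r} not in FPKM matrix")
    means = fpkm.by_genotype
    if genes is not None:
        means = means.loc[means.index.intersection(genes)]
    num = means[aneuploid].to_numpy()
    den = means[euploid].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(num / den)
    finite = np.isfinite(ratio)
    if (~finite).any():
        logger.info(
            "excluded %d genes with non-finite log2 ratio in %s vs %s",
            int((~finite).sum()),
            aneuploid,
            euploid,
        )
    idx = means.index[finite]
    out = pd.DataFrame(
        {
            "gene_id": idx,
            "chromosome": annotation.loc[idx, "chromosome"].to_numpy(),
            "position": gene_midpoints(annotation.loc[idx]).to_numpy(),
            "log2_ratio": ratio[finite],
            "contrast": f"{aneuploid}_vs_{euploid}",
        }
    )
    return out.sort_values(["chromosome", "position"], kind="stable").reset_index(
        drop=True
    )


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.1,
    degree: int = 2,
    eval_x: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Tri-cube-weighted local polynomial (loess) fit, no robustness pass.

    For each evaluation point the ``ceil(span * n)`` nearest data points
    (by |x - x0|) receive tri-cube weights ``(1 - (d/dmax)^3)^3`` and a
    degree-``degree`` polynomial is fitted by weighted least squares on
    centred x.  ``span`` is the fraction of points in each local window
    (default 0.1).  With fewer than ``degree + 2`` points a global
    polynomial is fitted instead, with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    eval_x = x if eval_x is None else np.asarray(eval_x, dtype=float)
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 1)
    if n < degree + 2:
        warnings.warn(
            f"only {n} points: falling back to a global degree-{min(degree, n - 1)} fit"
        )
        coeffs = np.polyfit(x, y, deg=min(degree, n - 1))
        return np.polyval(coeffs, eval_x)
    k = min(k, n)
    fitted = np.empty(len(eval_x))
    for i, x0 in enumerate(eval_x):
        d = np.abs(x - x0)
        local = np.argsort(d, kind="stable")[:k]
        dmax = d[local].max()
        if dmax == 0:
            fitted[i] = y[local].mean()
            continue
        w = (1.0 - (d[local] / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        # centred design matrix for conditioning at genomic coordinates
        t = (x[local] - x0) / dmax
        X = np.vander(t, N=degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[local] * sw, rcond=None)
        fitted[i] = beta[0]
    return fitted


def smooth_profile(
    profile: pd.DataFrame, span: float = 0.1, degree: int = 2
) -> pd.DataFrame:
    """Loess-smooth a ratio profile chromosome by chromosome.

    Returns the profile with an added ``smoothed`` column (the fitted
    log2 ratio at each gene position).
    """
    out = profile.copy()
    out["smoothed"] = np.nan
    for chrom, grp in profile.groupby("chromosome", sort=False):
        fit = loess_smooth(
            grp["position"].to_numpy(), grp["log2_ratio"].to_numpy(), span, degree
        )
        out.loc[grp.index, "smoothed"] = fit
    return out


def region_summary(
    profile: pd.DataFrame,
    chromosome: str,
    start: Optional[int] = None,
    end: Optional[int] = None,
    invert: bool = False,
) -> dict:
    """Median/mean log2 ratio of the genes in a chromosome or interval.

    ``invert=True`` summarises the genes on the chromosome *outside* the
    interval.  Raises ``ValueError`` when the region holds no genes.
    """
    on = profile["chromosome"] == chromosome
    if start is not None or end is not None:
        lo = -np.inf if start is None else start
        hi = np.inf if end is None else end
        inside = (profile["position"] >= lo) & (profile["position"] < hi)
        on = on & (~inside if invert else inside)
    elif invert:
        raise ValueError("invert requires an interval")
    sub = profile.loc[on, "log2_ratio"]
    if sub.empty:
        raise ValueError(f"no genes in region {chromosome}[{start}:{end}]")
    return {
        "chromosome": chromosome,
        "n_genes": int(len(sub)),
        "median_log2_ratio": float(sub.median()),
        "mean_log2_ratio": float(sub.mean()),
    }
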