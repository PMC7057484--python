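"""Per-gene Pearson tests of transcript abundance against chromosome dosage.

Each replicate of each genotype is one independent experimental unit;
the covariate is the gene's copy number under that genotype's karyotype
(e.g. 1 / 2 / 3 across a monosomic, euploid, trisomic panel).  Two-sided
p-values come from the t distribution with n_units - 2 degrees of
freedom and are BH-adjusted across all testable genes.  A gene is
untestable — and excluded from the adjustment — when its dosage or its
abundance is constant across units.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .core import Karyotype, dosage_matrix
from .quantify import FpkmMatrix


def dosage_correlation_test(
    fpkm: FpkmMatrix,
    annotation: pd.DataFrame,
    karyotypes: Mapping[str, Karyotype],
    genotypes: Sequence[str],
    genes: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Pearson r between per-replicate FPKM and chromosome dosage.

    Returns one record per gene with columns ``gene_id, chromosome, r, p,
    padj, n_units, dosages, testable``.  ``genes`` restricts to an
    expression-filtered subset.
    """
    design = fpkm.design
    used = design[design["genotype"].isin(genotypes)]
    if used["genotype"].nunique() < 2:
        raise ValueError("need at least two genotypes with samples")
    samples = used["sample"].tolist()
    values = fpkm.samples[samples]
    if genes is not None:
        values = values.loc[values.index.intersection(genes)]
    ann = annotation.loc[values.index]

    dmat = dosage_matrix({g: karyotypes[g] for g in genotypes}, ann)
    # per-unit dosage: genes x units
    dose = dmat[used["genotype"].to_numpy()].to_numpy(dtype=float)
    y = values.to_numpy(dtype=float)
    n_units = y.shape[1]

    yc = y - y.mean(axis=1, keepdims=True)
    dc = dose - dose.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    sd = np.sqrt((dc**2).sum(axis=1))
    testable = (sy > 0) & (sd > 0) & (n_units > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc * dc).sum(axis=1) / (sy * sd)
    r = np.where(testable, np.clip(r, -1.0, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_units - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = np.where(testable, 2.0 * stats.t.sf(np.abs(t), df=n_units - 2), np.nan)

    out = pd.DataFrame(
        {
            "gene_id": values.index,
            "chromosome": ann["chromosome"].to_numpy(),
            "r": r,
            "p": p,
            "padj": bh_adjust(p),
            "n_units": n_units,
            "dosages": [
                ",".join(map(str, sorted(set(row)))) for row in dmat.to_numpy()
            ],
            "testable": testable,
        }
    ).set_index("gene_id", drop=False)
    return out


def dosage_correlated_fraction(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    chromosome: str,
    start: Optional[int] = None,
    end: Optional[int] = None,
    alpha: float = 0.05,
) -> tuple[int, float]:
    """Count and fraction of region genes positively dosage-correlated.

    A gene counts when ``r > 0`` and ``padj < alpha``; the denominator is
    all tested genes in the region.  Raises on an empty region.
    """
    ann = annotation.loc[annotation.index.intersection(records.index)]
    on = ann["chromosome"] == chromosome
    if start is not None or end is not None:
        mid = (ann["start"] + ann["end"]) // 2
        lo = -np.inf if start is None else start
        hi = np.inf if end is None else end
        on = on & (mid >= lo) & (mid < hi)
    region = records.loc[ann.index[on]]
    region = region[region["testable"]]
    if region.empty:
        raise ValueError(f"no tested genes in region {chromosome}[{start}:{end}]")
    hits = int(((region["r"] > 0) & (region["padj"] < alpha)).sum())
    return hits, hits / len(region)
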