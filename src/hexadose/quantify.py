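"""Count-to-FPKM conversion, expression filtering and replicate QC.

FPKM (fragments per kilobase of gene per million mapped fragments) is
``1e9 * count / (sample_total * gene_length_nt)``.  Downstream analyses
work on genotype-averaged FPKM; the expression filter keeps genes whose
genotype-averaged FPKM exceeds unity in at least one genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FpkmMatrix:
    """Per-sample FPKM plus the replicate-averaged per-genotype matrix."""

    samples: pd.DataFrame  # genes x samples
    by_genotype: pd.DataFrame  # genes x genotypes (arithmetic mean of replicates)
    design: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.samples.index


def compute_fpkm(
    counts: pd.DataFrame, lengths: pd.Series, design: pd.DataFrame
) -> FpkmMatrix:
    """Convert a genes x samples count matrix to FPKM.

    ``lengths`` are gene lengths in nt (indexed by gene id); the
    denominator uses each sample's grand total of counted fragments.
    Raises ``ValueError`` for non-positive lengths or an all-zero sample.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    fpkm = counts.div(totals, axis=1).div(lengths, axis=0) * 1e9
    by_genotype = average_by_genotype(fpkm, design)
    return FpkmMatrix(samples=fpkm, by_genotype=by_genotype, design=design)


def average_by_genotype(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate sample columns per genotype."""
    genotype_of = design.set_index("sample")["genotype"]
    cols = values.columns.intersection(genotype_of.index)
    grouped = values[cols].T.groupby(genotype_of.loc[cols]).mean().T
    grouped.columns.name = None
    return grouped


def filter_expressed(fpkm: FpkmMatrix, threshold: float = 1.0) -> pd.Index:
    """Genes with genotype-averaged FPKM strictly above ``threshold`` in
    at least one genotype (the study's 'greater than unity' rule)."""
    keep = (fpkm.by_genotype > threshold).any(axis=1)
    return fpkm.by_genotype.index[keep]


def replicate_correlation(
    fpkm: FpkmMatrix, design: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2(FPKM + 1) between replicates.

    One row per within-genotype sample pair with columns
    ``genotype, sample_1, sample_2, r, r2``; zero-variance samples yield
    missing values with a logged warning.
    """
    design = fpkm.design if design is None else design
    log = np.log2(fpkm.samples + 1.0)
    rows = []
    for genotype, grp in design.groupby("genotype", sort=False):
        samples = [s for s in grp["sample"] if s in log.columns]
        for s1, s2 in combinations(samples, 2):
            x, y = log[s1].to_numpy(), log[s2].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                logger.warning(
                    "zero variance in %s or %s; correlation undefined", s1, s2
                )
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append((genotype, s1, s2, r, r * r))
    return pd.DataFrame(rows, columns=["genotype", "sample_1", "sample_2", "r", "r2"])
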