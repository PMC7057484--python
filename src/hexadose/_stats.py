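"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untestable features) are passed through as NaN and do
    not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
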