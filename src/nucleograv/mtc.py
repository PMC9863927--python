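"""Multiple-testing helpers shared across the statistics modules.

Benjamini-Hochberg adjustment is delegated to statsmodels; star codes follow
the usual convention of one star per significance threshold crossed.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

#: two-level star thresholds used for chromosome and fold-change reports
TWO_LEVEL = (0.05, 0.01)
#: four-level star thresholds used for biotype group tests
FOUR_LEVEL = (0.05, 0.01, 0.001, 0.0001)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment.

    NaN entries are passed through untouched and do not count toward the
    family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def star_code(padj: float, thresholds: Sequence[float] = TWO_LEVEL) -> str:
    """Return 'ns', '*', '**', ... according to how many thresholds padj beats.

    ``thresholds`` must be strictly decreasing (e.g. 0.05, 0.01). A missing
    adjusted p-value yields the empty string so callers can distinguish
    "tested, not significant" from "not tested".
    """
    if padj is None or np.isnan(padj):
        return ""
    n = sum(1 for t in thresholds if padj < t)
    return "*" * n if n else "ns"
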