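"""Small shared statistical helpers (multiple-testing, two-group tests)."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "welch_t"]


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x: np.ndarray, y: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t-test along ``axis``; returns (t, p)."""
    res = sps.ttest_ind(x, y, axis=axis, equal_var=False)
    return np.asarray(res.statistic), np.asarray(res.pvalue)
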