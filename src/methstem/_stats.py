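"""Shared statistical helpers: rank-sum tests, BH adjustment, tricube kernel."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "bh_adjust", "tricube", "log_normalize"]

#: combined sample size at or below which the exact Mann-Whitney null is used
EXACT_N_MAX = 25


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Uses the exact Mann-Whitney U distribution when the combined sample is
    small (n <= 25) and tie-free, otherwise the tie-corrected normal
    approximation. Degenerate inputs (either sample empty, or all values
    identical across both samples) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return 1.0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = x.size + y.size
    has_ties = np.unique(pooled).size < n
    method = "exact" if (n <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries are passed through as NaN and do not count toward the
    family size.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(pm, method="fdr_bh")[1]
    return out


def tricube(d: np.ndarray, bandwidth: float) -> np.ndarray:
    """Tricube kernel weights (1 - |d/h|^3)^3, zero outside |d| >= h."""
    u = np.abs(np.asarray(d, dtype=float)) / float(bandwidth)
    w = np.zeros_like(u)
    inside = u < 1.0
    w[inside] = (1.0 - u[inside] ** 3) ** 3
    return w


def log_normalize(counts, scale: float = 1e4) -> np.ndarray:
    """Log-normalize a genes x cells count matrix.

    Each cell's counts are scaled to ``scale`` total, then log1p-transformed.
    Cells with zero total counts are left at zero.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(counts / safe * scale)
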