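"""Shared statistical helpers: BH adjustment, vectorized two-sample t-tests
with a zero-variance convention, and vectorized Spearman correlation of many
columns against one vector."""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import stats
from scipy.stats import rankdata


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def rowwise_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test per row of ``a`` (rows x samples_a) vs ``b``.

    Rows constant within both groups get t = 0, p = 1 by convention and are
    flagged in the returned boolean array.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    const = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    t[const] = 0.0
    p[const] = 1.0
    # residual NaNs (e.g. one group constant, both means equal) -> no evidence
    nan = np.isnan(p)
    t[nan] = 0.0
    p[nan] = 1.0
    return t, p, const


def spearman_columns_vs_vector(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of every column of X against y.

    Uses the t-distribution approximation on n-2 degrees of freedom (the
    default large-sample p of common implementations).  Zero-variance
    columns yield rho = NaN, p = NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n != y.shape[0]:
        raise ValueError("length mismatch between matrix rows and vector")
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(X, axis=0)
    ry = rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p
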