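"""Shared nonparametric statistics: rank tests, Spearman correlation, BH-FDR.

Thin, contract-pinning wrappers around :mod:`scipy.stats`.  Spearman
correlation additionally has a vectorised row-wise form used for the
1000-pair cross-omics screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: minimum complete observations for a Spearman correlation to be reported
MIN_N_CORRELATION = 5


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def rank_sum_test(a, b, *, method: str = "auto") -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    With ``method='auto'`` scipy uses the exact null distribution for small
    tie-free samples and the tie-corrected normal approximation otherwise.
    Degenerate input (all values identical across both groups) yields p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return RankTestResult(a.size * b.size / 2.0, 1.0, float(np.median(a)), float(np.median(b)), a.size, b.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)),
        float(np.median(a)), float(np.median(b)), a.size, b.size,
    )


def signed_rank_test(diff, *, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired differences against 0.

    Zero differences are dropped (Wilcoxon's convention); an all-zero vector
    returns (0, 1.0).
    """
    diff = np.asarray(diff, float)
    if np.all(diff == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided", mode=method, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho with average-rank ties and the two-sided t-approximation p.

    Pairs with a missing value in either vector are dropped; returns
    ``(nan, nan, n)`` when fewer than :data:`MIN_N_CORRELATION` complete
    pairs remain.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < MIN_N_CORRELATION:
        return float("nan"), float("nan"), n
    rho, p = _spearman_t(x[ok], y[ok])
    return rho, p, n


def spearman_rowwise(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-row Spearman rho and t-approximation p for paired matrices.

    ``X`` and ``Y`` share shape (n_rows, n_subjects); row i of the result is
    the across-subject correlation of ``X[i]`` with ``Y[i]``.
    """
    if X.shape != Y.shape:
        raise ValueError("matrices must share shape")
    n = X.shape[1]
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(Y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rx * ry).sum(axis=1) / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    p = _t_pvalue(rho, n)
    return rho, p


def _spearman_t(x, y) -> tuple[float, float]:
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):  # zero variance in a vector
        return float("nan"), float("nan")
    return float(rho), float(_t_pvalue(np.array([rho]), x.size)[0])


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t distribution with n-2 df."""
    if n < 3:
        return np.full_like(rho, np.nan, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values; q >= p elementwise and monotone in p."""
    p = np.asarray(p_values, float)
    return stats.false_discovery_control(p, method="bh")
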