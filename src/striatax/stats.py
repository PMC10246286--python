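"""Shared statistical primitives: rank-sum testing and BH adjustment.

The rank-sum test switches between an exact permutation null (computed by a
subset-sum dynamic program over doubled midranks, equivalent to full
enumeration and valid under ties) and the usual normal approximation with
tie correction.  The exact route is used whenever both groups are small.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test", "bh_adjust"]

#: default maximum per-group size for the exact permutation null
EXACT_MAX = 8


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_ranksum_p(ranks: np.ndarray, n_x: int, t_obs: float) -> float:
    """Two-sided exact permutation p-value for the rank-sum statistic.

    Counts, over all C(N, n_x) assignments of group labels, the assignments
    whose rank-sum deviates from the permutation mean at least as much as the
    observed one.  Midranks are doubled so all weights are integers; the count
    per (subset size, weight sum) is accumulated by dynamic programming, which
    enumerates the same distribution as brute force.
    """
    w = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
    total = int(w.sum())
    n = len(w)
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n_x + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for wi in w:
        for k in range(n_x, 0, -1):  # descending: each item used at most once
            dp[k, wi:] += dp[k - 1, : total + 1 - wi]
    counts = dp[n_x]
    n_total = counts.sum()
    sums = np.arange(total + 1) / 2.0
    mu = float((sums * counts).sum() / n_total)
    dev = np.abs(sums - mu)
    d_obs = abs(t_obs - mu)
    p = counts[dev >= d_obs - 1e-9].sum() / n_total
    return float(min(1.0, p))


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    exact_max: int = EXACT_MAX,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(rank_sum_of_x, p_two_sided)``.  Uses the exact permutation
    null when ``len(x) <= exact_max and len(y) <= exact_max``, otherwise a
    normal approximation with tie correction (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x == 0 or n_y == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    t_obs = float(ranks[:n_x].sum())

    if n_x <= exact_max and n_y <= exact_max:
        return t_obs, _exact_ranksum_p(ranks, n_x, t_obs)

    n = n_x + n_y
    mu = n_x * (n + 1) / 2.0
    # tie correction for the rank-sum variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return t_obs, 1.0
    z = (t_obs - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return t_obs, float(min(1.0, p))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out
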