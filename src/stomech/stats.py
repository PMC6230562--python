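"""Rank-sum (Mann–Whitney–Wilcoxon) testing used as the model-acceptance
criterion: a candidate wall material is accepted when simulated and measured
open geometries are statistically indistinguishable (p > 0.05).

Midranks handle ties; small pooled samples (n+m ≤ 12 by default) are tested
by exact enumeration of all label assignments, larger ones by the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np

EXACT_MAX = 12  # pooled size up to which the exact permutation null is used


@dataclass
class RankSumResult:
    U: float
    p: float
    method: str  # "exact" or "normal-approx"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U of x over y with midrank tie handling:
    U = #{(i,j): x_i > y_j} + ½·#{ties}."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def rank_sum_test(x, y, exact_max: int = EXACT_MAX) -> RankSumResult:
    """Two-sided Mann–Whitney–Wilcoxon test.

    Exact mode enumerates every split of the pooled values into groups of
    sizes (n, m), so it is correct under ties; the two-sided p doubles the
    smaller tail (capped at 1). The normal approximation applies midrank tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples need at least one observation")
    u_obs = _u_statistic(x, y)

    if n + m <= exact_max:
        pooled = np.concatenate([x, y])
        total = comb(n + m, n)
        le = ge = 0
        idx = np.arange(n + m)
        for subset in combinations(idx, n):
            sel = np.zeros(n + m, dtype=bool)
            sel[list(subset)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            if u <= u_obs + 1e-12:
                le += 1
            if u >= u_obs - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return RankSumResult(U=u_obs, p=p, method="exact")

    N = n + m
    mu = n * m / 2.0
    # midrank tie correction
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1.0))
    sigma2 = n * m / 12.0 * ((N + 1.0) - tie_term)
    if sigma2 <= 0:
        return RankSumResult(U=u_obs, p=1.0, method="normal-approx")
    # continuity correction toward the mean
    z = max((abs(u_obs - mu) - 0.5) / sqrt(sigma2), 0.0)
    p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))
    return RankSumResult(U=u_obs, p=p, method="normal-approx")
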