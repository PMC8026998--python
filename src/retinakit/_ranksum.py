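"""Shared Wilcoxon rank-sum / Mann–Whitney engine.

Exact two-sided p by tie-aware enumeration of the rank-sum null distribution
when both groups have at most ``EXACT_MAX`` observations; tie-corrected
normal approximation (scipy) otherwise.  Ties are handled by midranks in
both branches.

The exact branch does not enumerate subsets explicitly (infeasible already at
25 + 25); it computes the identical distribution with a shift-algorithm
dynamic programme over doubled midranks, which are integers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

EXACT_MAX = 25


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    z = np.concatenate([x, y])
    n, big_n = len(x), len(z)
    # doubled midranks are integers even with ties
    d = np.rint(2.0 * stats.rankdata(z)).astype(np.int64)
    w_obs = int(d[:n].sum())
    total = int(d.sum())  # = N(N+1)
    mean2 = n * (big_n + 1)  # E[W] on the doubled scale

    # f[k, s] = number of size-k subsets of d with doubled-rank sum s
    f = np.zeros((n + 1, total + 1), dtype=np.float64)
    f[0, 0] = 1.0
    for di in d:
        upper = min(n, big_n)  # rows to update, top-down in k
        for k in range(upper - 1, -1, -1):
            row = f[k]
            if not row.any():
                continue
            f[k + 1, di:] += row[: total + 1 - di]
    dist = f[n]
    n_subsets = dist.sum()
    dev = abs(w_obs - mean2)
    s = np.arange(total + 1)
    p = dist[np.abs(s - mean2) >= dev - 1e-9].sum() / n_subsets
    return float(min(p, 1.0))


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (rank-sum statistic of x, p value).

    Exact when both groups have <= 25 observations, tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    w = float(stats.rankdata(combined)[: len(x)].sum())
    if np.all(combined == combined[0]):
        return w, 1.0
    if len(x) <= EXACT_MAX and len(y) <= EXACT_MAX:
        p = _exact_two_sided_p(x, y)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return w, p
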