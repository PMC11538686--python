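"""Independent reference implementations used only to check the package.

These deliberately use brute force / exact enumeration, not the code paths
under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def kmeans_1d_exact(values: np.ndarray, k: int) -> list[np.ndarray]:
    """Globally optimal 1-D k-means by dynamic programming.

    Sorts the values and exploits the fact that optimal 1-D clusters are
    contiguous in sorted order; O(k n^2).  Returns the list of clusters as
    arrays of *original* indices, ordered by increasing cluster mean.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    x = values[order]
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):  # SSE of x[i:j]
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        return s2 - s * s / (j - i)

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = dp[c - 1, i] + cost(i, j)
                if v < best:
                    best, arg = v, i
            dp[c, j] = best
            back[c, j] = arg
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds = bounds[::-1]
    clusters = [order[bounds[c] : bounds[c + 1]] for c in range(k)]
    return clusters


def hypergeom_sf_bruteforce(universe: int, n_target: int, n_draw: int, obs: int) -> float:
    """P(overlap >= obs) by exhaustive enumeration of all draws.

    Enumerates every ``n_draw``-subset of a ``universe``-gene pool whose
    first ``n_target`` elements are the target set.
    """
    target = set(range(n_target))
    total = 0
    hits = 0
    for draw in combinations(range(universe), n_draw):
        total += 1
        if len(target.intersection(draw)) >= obs:
            hits += 1
    return hits / total


def exact_permutation_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided permutation p-value for the difference of group means by
    complete enumeration of group-label assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    obs = abs(a.mean() - b.mean())
    idx = range(pooled.size)
    total = 0
    hits = 0
    for g1 in combinations(idx, n1):
        total += 1
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(g1)] = True
        d = abs(pooled[mask].mean() - pooled[~mask].mean())
        if d >= obs - 1e-12:
            hits += 1
    return hits / total
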