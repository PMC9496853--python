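"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the defining formulas, without
reusing any code path from the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def bicor_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors, straight from the formula."""

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:  # Pearson fallback
            return v - np.mean(v)
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        return (v - med) * w

    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    denom = math.sqrt((a**2).sum()) * math.sqrt((b**2).sum())
    return float((a * b).sum() / denom)


def bicor_matrix_oracle(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c[i, j] = c[j, i] = bicor_pair(x[i], x[j])
    return c


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    a = a.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def connectivity_oracle(a: np.ndarray, idx: list[int]) -> np.ndarray:
    """Per-gene sum of adjacency to the other module genes."""
    out = []
    for i in idx:
        out.append(sum(a[i, j] for j in idx if j != i))
    return np.array(out)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


def hypergeom_oracle(N: int, p: int, c: int, i: int) -> float:
    """Upper-tail hypergeometric probability via log-factorials."""

    def lchoose(n, k):
        if k < 0 or k > n:
            return -math.inf
        return (
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        )

    total = 0.0
    for k in range(i, min(c, p) + 1):
        total += math.exp(
            lchoose(c, k) + lchoose(N - c, p - k) - lchoose(N, p)
        )
    return total


def hypergeom_enumeration(N: int, p: int, c: int, i: int) -> float:
    """Exhaustive enumeration over all C(N, p) draws of size p."""
    candidate = set(range(c))
    hits = 0
    total = 0
    for draw in combinations(range(N), p):
        total += 1
        if len(candidate.intersection(draw)) >= i:
            hits += 1
    return hits / total


def spearman_oracle(x: np.ndarray) -> np.ndarray:
    """Rank-transform rows then Pearson."""
    r = np.vstack([rankdata(row) for row in x])
    return np.corrcoef(r)


def ols_two_group_oracle(y: np.ndarray, ind: np.ndarray) -> tuple[float, float]:
    """Closed-form difference-in-means slope + equal-variance t test p."""
    from scipy import stats

    y1, y0 = y[ind == 1], y[ind == 0]
    beta = y1.mean() - y0.mean()
    t, p = stats.ttest_ind(y1, y0, equal_var=True)
    return float(beta), float(p)
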