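"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths (and where possible the libraries)
used by the package: quantiles by manual sort-and-interpolate, shortest
paths by exhaustive simple-path enumeration, clustering by triangle
enumeration, modularity by exhaustive partition search, assortativity by
Newman's explicit sum formula, regression slopes by normal equations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_peak_width(values, lo_pct=5.0, hi_pct=95.0) -> float:
    """Type-7 quantile difference by manual sorting and interpolation."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def q(p):
        h = (n - 1) * p / 100.0
        f = math.floor(h)
        c = min(f + 1, n - 1)
        return v[f] + (h - f) * (v[c] - v[f])

    return q(hi_pct) - q(lo_pct)


def brute_shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths over lengths 1/w by simple-path enumeration."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)

    def dfs(node, target, visited, length):
        nonlocal best
        if length >= best:
            return
        if node == target:
            best = length
            return
        for k in range(n):
            if W[node, k] > 0 and k not in visited:
                dfs(k, target, visited | {k}, length + 1.0 / W[node, k])

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            dfs(i, j, {i}, 0.0)
            D[i, j] = best
    return D


def brute_global_efficiency(W: np.ndarray) -> float:
    D = brute_shortest_paths(W)
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def brute_char_path_length(W: np.ndarray) -> float:
    D = brute_shortest_paths(W)
    vals = [D[i, j] for i in range(W.shape[0]) for j in range(W.shape[0])
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals))


def brute_nodal_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela clustering by explicit triangle enumeration."""
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        tot = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if W[j, h] > 0:
                tot += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        C[i] = 2.0 * tot / (k * (k - 1))
    return C


def _partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_modularity_max(W: np.ndarray) -> float:
    """Exhaustive maximum of Newman's weighted Q over all partitions."""
    n = W.shape[0]
    two_m = W.sum()
    s = W.sum(axis=1)
    best = -np.inf
    for part in _partitions(range(n)):
        q = 0.0
        for block in part:
            for i in block:
                for j in block:
                    q += W[i, j] - s[i] * s[j] / two_m
        best = max(best, q / two_m)
    return best


def newman_assortativity(W: np.ndarray) -> float:
    """Newman's edge-sum formula over strengths (one term per edge)."""
    s = W.sum(axis=1)
    edges = [(i, j) for i in range(W.shape[0]) for j in range(i + 1, W.shape[0])
             if W[i, j] > 0]
    M = len(edges)
    sum_jk = sum(s[i] * s[j] for i, j in edges) / M
    sum_half = sum(0.5 * (s[i] + s[j]) for i, j in edges) / M
    sum_sq = sum(0.5 * (s[i] ** 2 + s[j] ** 2) for i, j in edges) / M
    denom = sum_sq - sum_half**2
    return (sum_jk - sum_half**2) / denom


def brute_hierarchy(W: np.ndarray) -> float:
    """-slope of log C on log k by explicit normal equations."""
    k = (W > 0).sum(axis=1).astype(float)
    C = brute_nodal_clustering(W)
    ok = (k > 1) & (C > 0)
    x = np.log(k[ok])
    y = np.log(C[ok])
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return -slope


def partial_corr_1cov(x, y, z) -> float:
    """First-order partial correlation by the recursive closed form."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))


def brute_fdr_bh(p):
    """Step-up adjusted p-values computed by the textbook recipe."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev)
        adj[i] = val
        prev = val
    return adj


def rank_sum_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney rank-sum statistic (tie = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))
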