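"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive — triple loops, Floyd-Warshall,
explicit sum formulas — and shares no code with the implementation
under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def clustering_triple_loop(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for i in range(k):
            for j in range(i + 1, k):
                if a[nbrs[i], nbrs[j]]:
                    links += 1
        out[v] = 2 * links / (k * (k - 1))
    return out


def flow_bruteforce(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = a.shape[0]
    norm = np.zeros(n)
    raw = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        open_pairs = 0
        for i, j in itertools.combinations(nbrs, 2):
            if not a[i, j]:
                open_pairs += 1
        raw[v] = open_pairs
        norm[v] = open_pairs / (k * (k - 1) / 2)
    return norm, raw


def efficiency_floyd_warshall(a: np.ndarray) -> tuple[float, float]:
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    inv = 0.0
    tot = 0.0
    n_conn = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            n_pairs += 1
            if np.isfinite(d[i, j]):
                inv += 1.0 / d[i, j]
                tot += d[i, j]
                n_conn += 1
    eff = inv / n_pairs if n_pairs else 0.0
    cpl = tot / n_conn if n_conn else float("nan")
    return eff, cpl


def assortativity_newman_sum(a: np.ndarray) -> float:
    """Newman's edge-end degree correlation via the explicit sums."""
    deg = a.sum(axis=1)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.array(xs, float), np.array(ys, float)
    m = len(xs)
    num = (xs * ys).mean() - xs.mean() * ys.mean()
    den = (xs**2).mean() - xs.mean() ** 2
    if den == 0:
        return float("nan")
    # symmetric edge-end lists: var(x) == var(y)
    return float(num / den)


def spearman_rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Rank by sorting with midranks, then the product-moment formula."""

    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    den = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / den) if den else 0.0


def kruskal_wallis_formula(*groups) -> float:
    """H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), with tie correction."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_tot = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n_tot)
    i = 0
    sp = pooled[order]
    while i < n_tot:
        j = i
        while j + 1 < n_tot and sp[j + 1] == sp[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g, float)
        r = ranks[start : start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n_tot**3 - n_tot)
    return h / tie if tie > 0 else 0.0


def pinv_svd(a: np.ndarray, rcond: float) -> np.ndarray:
    """Moore-Penrose pseudoinverse assembled from an explicit SVD."""
    u, s, vt = np.linalg.svd(a)
    cutoff = rcond * s.max() if s.size else 0.0
    s_inv = np.array([1.0 / x if x > cutoff else 0.0 for x in s])
    return vt.T @ np.diag(s_inv) @ u.T
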