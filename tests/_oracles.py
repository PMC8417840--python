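"""Independent brute-force oracles for graph metrics and FDR.

These deliberately avoid the library routines the package itself uses:
distances come from a hand-written Floyd-Warshall triple loop, betweenness
from exhaustive simple-path enumeration, clustering from a direct evaluation
of the geometric-mean triangle formula, and FDR from checking every step-up
threshold.
"""

from __future__ import annotations

import numpy as np


def random_weight_matrix(n: int, rng: np.random.Generator, p_edge: float = 0.5) -> np.ndarray:
    """Random symmetric positive weight matrix with zero diagonal."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(0.2, 1.0)
    return W


def brute_strength(W: np.ndarray) -> np.ndarray:
    return np.array([sum(W[i, j] for j in range(W.shape[0])) for i in range(W.shape[0])])


def brute_onnela_clustering(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    Wh = W / wmax
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and W[j, h] > 0:
                    acc += (Wh[i, j] * Wh[i, h] * Wh[j, h]) ** (1.0 / 3.0)
        c[i] = acc / (k * (k - 1))
    return c


def brute_floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs 1/w distances by the textbook triple loop."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _all_simple_paths(W: np.ndarray, s: int, t: int) -> list[list[int]]:
    n = W.shape[0]
    paths: list[list[int]] = []

    def dfs(node: int, visited: list[int]) -> None:
        if node == t:
            paths.append(visited.copy())
            return
        for nxt in range(n):
            if W[node, nxt] > 0 and nxt not in visited:
                visited.append(nxt)
                dfs(nxt, visited)
                visited.pop()

    dfs(s, [s])
    return paths


def brute_betweenness(W: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    """Raw betweenness by enumerating every simple path between every pair,
    keeping the minimum-length ones, and crediting interior nodes
    fractionally.  Each unordered pair counts once."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_simple_paths(W, s, t)
            if not paths:
                continue
            lengths = [sum(1.0 / W[p[k], p[k + 1]] for k in range(len(p) - 1)) for p in paths]
            dmin = min(lengths)
            shortest = [p for p, ln in zip(paths, lengths) if ln <= dmin * (1 + rel_tol)]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def brute_char_path_length(D: np.ndarray) -> tuple[float, int]:
    n = D.shape[0]
    finite, infinite = [], 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(D[i, j]):
                finite.append(D[i, j])
            else:
                infinite += 1
    return float(np.mean(finite)), infinite


def brute_bh_fdr(p: np.ndarray, q: float) -> np.ndarray:
    """Step-up rejection mask by explicitly checking every threshold."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject
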