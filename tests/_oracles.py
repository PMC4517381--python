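"""Independent brute-force oracles for shortest-path structure.

Exhaustive simple-path enumeration (feasible for graphs of ~6 nodes):
shortest-path lengths, counts of distinct shortest paths, and counts of
shortest paths through each interior node, computed without BFS so they
can check the package's BFS-based implementation.
"""

from __future__ import annotations

import numpy as np


def _all_simple_paths(adj: np.ndarray, src: int, dst: int) -> list[tuple[int, ...]]:
    n = adj.shape[0]
    out: list[tuple[int, ...]] = []
    stack = [(src, (src,))]
    while stack:
        u, path = stack.pop()
        if u == dst:
            out.append(path)
            continue
        for v in range(n):
            if adj[u, v] and v not in path:
                stack.append((v, path + (v,)))
    return out


def brute_force_paths(adj: np.ndarray):
    """Return (lengths, sigma, sigma_through) by exhaustive enumeration.

    lengths[j, k]: shortest-path length (inf if disconnected, 0 diagonal)
    sigma[j, k]: number of distinct shortest j-k paths
    sigma_through[i][j][k]: shortest j-k paths with i as an interior node
    """
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    lengths = np.full((n, n), np.inf)
    np.fill_diagonal(lengths, 0.0)
    sigma = np.zeros((n, n), dtype=int)
    np.fill_diagonal(sigma, 1)
    through = np.zeros((n, n, n), dtype=int)
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            paths = _all_simple_paths(adj, j, k)
            if not paths:
                continue
            lmin = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == lmin]
            lengths[j, k] = lmin
            sigma[j, k] = len(shortest)
            for p in shortest:
                for i in p[1:-1]:
                    through[i, j, k] += 1
    return lengths, sigma, through


def brute_force_betweenness(adj: np.ndarray) -> np.ndarray:
    """Fractional betweenness over unordered pairs, from enumerated paths."""
    n = adj.shape[0]
    _, sigma, through = brute_force_paths(adj)
    b = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or sigma[j, k] == 0:
                    continue
                b[i] += through[i, j, k] / sigma[j, k]
    return b


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric zero-diagonal 0/1 matrix of an Erdos-Renyi G(n, p) draw."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    return (adj | adj.T).astype(int)
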