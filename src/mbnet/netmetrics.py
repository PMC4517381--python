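"""Topological indices of a multi-brain network.

Nodes are brains (one ROI per participant); edges are thresholded
inter-brain synchronization.  The indices follow the standard
graph-theoretic definitions on a simple undirected graph G with N nodes
and shortest-path lengths l_ij:

* nodal global efficiency   E_i = (1/(N-1)) sum_{j != i} 1/l_ij
* nodal local efficiency    efficiency of the subgraph induced by i's
  neighbors, normalized by ordered pairs N_Gi (N_Gi - 1); 0 when the
  node has fewer than 2 neighbors
* network global efficiency mean of 1/l_ij over all ordered pairs, which
  equals the mean of the nodal global efficiencies
* network local efficiency  mean over nodes of the nodal local efficiency
* betweenness               B_i = sum over unordered pairs {j, k} of
  sigma_jk(i) / sigma_jk, the fraction of shortest j-k paths through i

Disconnected pairs contribute 0 to efficiencies (1/inf = 0) and to
betweenness (sigma_jk = 0).  Shortest paths are computed exactly by
breadth-first search with path counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io_formats import AdjacencyMatrix, MetricsReport

__all__ = [
    "Graph",
    "PathStats",
    "all_pairs_paths",
    "nodal_global_efficiency",
    "nodal_local_efficiency",
    "network_global_efficiency",
    "network_local_efficiency",
    "betweenness",
    "degree",
    "clustering_coefficient",
    "characteristic_path_length",
    "assortativity",
    "metrics_report",
]


@dataclass
class Graph:
    """Simple undirected graph with labeled nodes."""

    labels: list[str]
    adj: np.ndarray

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj).astype(bool)
        n = len(self.labels)
        if self.adj.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}")
        if not np.array_equal(self.adj, self.adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adj)):
            raise ValueError("no self loops allowed")
        self._nbrs = [np.flatnonzero(row) for row in self.adj]

    @classmethod
    def from_adjacency(cls, am: AdjacencyMatrix) -> "Graph":
        return cls(labels=list(am.labels), adj=am.values.astype(bool))

    @classmethod
    def from_edges(
        cls, labels: Iterable[str], edges: Iterable[tuple[int, int]]
    ) -> "Graph":
        labels = [str(x) for x in labels]
        n = len(labels)
        adj = np.zeros((n, n), dtype=bool)
        for i, j in edges:
            if i == j:
                raise ValueError("no self loops allowed")
            adj[i, j] = adj[j, i] = True
        return cls(labels=labels, adj=adj)

    @property
    def n(self) -> int:
        return len(self.labels)

    def neighbors(self, i: int) -> np.ndarray:
        return self._nbrs[i]

    def subgraph(self, nodes: np.ndarray) -> "Graph":
        nodes = np.asarray(nodes, dtype=int)
        return Graph(
            labels=[self.labels[i] for i in nodes],
            adj=self.adj[np.ix_(nodes, nodes)],
        )


@dataclass
class PathStats:
    """Exact shortest-path structure of a graph.

    lengths[j, k]
        shortest-path length (``inf`` for disconnected pairs, 0 diagonal).
    sigma[j, k]
        number of distinct shortest j-k paths (0 when disconnected).
    sigma_through[i, j, k]
        number of shortest j-k paths passing through the interior node i
        (0 whenever i is an endpoint).
    """

    lengths: np.ndarray
    sigma: np.ndarray
    sigma_through: np.ndarray


def _bfs_counts(g: Graph, src: int) -> tuple[np.ndarray, np.ndarray]:
    n = g.n
    dist = np.full(n, np.inf)
    sigma = np.zeros(n, dtype=np.int64)
    dist[src] = 0
    sigma[src] = 1
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt: list[int] = []
        for u in frontier:
            for v in g.neighbors(u):
                v = int(v)
                if dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(v)
                if dist[v] == d:
                    sigma[v] += sigma[u]
        frontier = nxt
    return dist, sigma


def all_pairs_paths(g: Graph) -> PathStats:
    """BFS shortest-path lengths and path counts for every node pair.

    ``sigma_through`` uses the factorization sigma_jk(i) =
    sigma_ji * sigma_ik when l_ji + l_ik = l_jk (and 0 otherwise), valid
    because every shortest j-k path through i is a shortest j-i path
    concatenated with a shortest i-k path.
    """
    n = g.n
    lengths = np.zeros((n, n))
    sigma = np.zeros((n, n), dtype=np.int64)
    for s in range(n):
        lengths[s], sigma[s] = _bfs_counts(g, s)
    through = np.zeros((n, n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if j == i or lengths[j, i] == np.inf:
                continue
            for k in range(n):
                if k in (i, j) or lengths[i, k] == np.inf:
                    continue
                if lengths[j, i] + lengths[i, k] == lengths[j, k]:
                    through[i, j, k] = sigma[j, i] * sigma[i, k]
    return PathStats(lengths=lengths, sigma=sigma, sigma_through=through)


def _inv_lengths(lengths: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / lengths
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def nodal_global_efficiency(
    g: Graph, i: int, paths: PathStats | None = None
) -> float:
    """Mean inverse shortest-path length from node i to all others."""
    if g.n < 2:
        raise ValueError("nodal global efficiency needs at least 2 nodes")
    paths = paths or all_pairs_paths(g)
    return float(_inv_lengths(paths.lengths)[i].sum() / (g.n - 1))


def nodal_local_efficiency(g: Graph, i: int) -> float:
    """Efficiency of the subgraph induced by i's neighbors.

    Paths are confined to the neighbor subgraph.  Nodes with fewer than
    two neighbors have no pairs to average over and get 0.
    """
    nbrs = g.neighbors(i)
    k = len(nbrs)
    if k < 2:
        return 0.0
    sub = g.subgraph(nbrs)
    inv = _inv_lengths(all_pairs_paths(sub).lengths)
    return float(inv.sum() / (k * (k - 1)))


def network_global_efficiency(g: Graph, paths: PathStats | None = None) -> float:
    """Mean inverse shortest-path length over all ordered pairs; equals
    the mean of the nodal global efficiencies."""
    if g.n < 2:
        raise ValueError("network global efficiency needs at least 2 nodes")
    paths = paths or all_pairs_paths(g)
    return float(_inv_lengths(paths.lengths).sum() / (g.n * (g.n - 1)))


def network_local_efficiency(g: Graph) -> float:
    """Mean over nodes of the nodal local efficiency."""
    return float(np.mean([nodal_local_efficiency(g, i) for i in range(g.n)]))


def betweenness(g: Graph, i: int, paths: PathStats | None = None) -> float:
    """Fractional betweenness of node i over unordered pairs {j, k}."""
    paths = paths or all_pairs_paths(g)
    total = 0.0
    for j in range(g.n):
        for k in range(j + 1, g.n):
            if i in (j, k) or paths.sigma[j, k] == 0:
                continue
            total += paths.sigma_through[i, j, k] / paths.sigma[j, k]
    return total


def degree(g: Graph, i: int) -> int:
    return int(g.adj[i].sum())


def clustering_coefficient(g: Graph, i: int) -> float:
    """Fraction of the node's neighbor pairs that are themselves linked."""
    nbrs = g.neighbors(i)
    d = len(nbrs)
    if d < 2:
        return 0.0
    links = int(g.adj[np.ix_(nbrs, nbrs)].sum()) // 2
    return links / (d * (d - 1) / 2)


def characteristic_path_length(
    g: Graph, paths: PathStats | None = None
) -> tuple[float, bool]:
    """Mean shortest-path length over connected unordered pairs.

    Returns ``(value, connected)``; on a disconnected graph the mean is
    taken over connected pairs only and a warning is issued.  ``nan``
    when no pair is connected.
    """
    paths = paths or all_pairs_paths(g)
    iu = np.triu_indices(g.n, 1)
    vals = paths.lengths[iu]
    finite = np.isfinite(vals)
    connected = bool(finite.all())
    if not connected:
        warnings.warn(
            "graph is disconnected; characteristic path length computed "
            "over connected pairs only",
            stacklevel=2,
        )
    if not finite.any():
        return float("nan"), connected
    return float(vals[finite].mean()), connected


def assortativity(g: Graph) -> float:
    """Pearson correlation of end-point degrees over edges (both
    orientations).  ``nan`` with a warning when degenerate (e.g. all
    degrees equal)."""
    deg = g.adj.sum(axis=1)
    ii, jj = np.nonzero(np.triu(g.adj, 1))
    if len(ii) == 0:
        warnings.warn("assortativity undefined: graph has no edges", stacklevel=2)
        return float("nan")
    a = np.concatenate([deg[ii], deg[jj]]).astype(float)
    b = np.concatenate([deg[jj], deg[ii]]).astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            "assortativity undefined: all edge end-point degrees equal",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def metrics_report(g: Graph) -> MetricsReport:
    """All nodal and network indices assembled into one report."""
    paths = all_pairs_paths(g)
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cpl, connected = characteristic_path_length(g, paths)
        assort = assortativity(g)
        flags.extend(str(w.message) for w in caught)
    nodal = {
        "degree": np.array([degree(g, i) for i in range(g.n)], dtype=float),
        "global_efficiency": np.array(
            [nodal_global_efficiency(g, i, paths) for i in range(g.n)]
        ),
        "local_efficiency": np.array(
            [nodal_local_efficiency(g, i) for i in range(g.n)]
        ),
        "betweenness": np.array(
            [betweenness(g, i, paths) for i in range(g.n)]
        ),
        "clustering_coefficient": np.array(
            [clustering_coefficient(g, i) for i in range(g.n)]
        ),
    }
    network = {
        "global_efficiency": network_global_efficiency(g, paths),
        "local_efficiency": network_local_efficiency(g),
        "characteristic_path_length": cpl,
        "assortativity": assort,
    }
    return MetricsReport(
        labels=list(g.labels), nodal=nodal, network=network, flags=flags
    )
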