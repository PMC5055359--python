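"""Complexity metrics for weighted spatial graphs.

Conventions follow the brain-connectivity literature: in weighted mode an
edge's connection length is its Euclidean length in um (connection weight is
the inverse distance, so shortest paths minimise summed length); binary mode
sets every length to 1.  Global efficiency is the mean inverse shortest-path
length over ordered node pairs (unreachable pairs contribute 0); local
efficiency of a node is the global efficiency of the subgraph induced by its
neighbours, with paths restricted to that subgraph.  Node betweenness uses
Brandes' accumulation with fractional counting over equal-length shortest
paths, normalised by (n-1)(n-2)/2.  Assortativity is the Pearson correlation
of endpoint degrees over the symmetrised edge list.

All-pairs shortest paths are delegated to :mod:`scipy.sparse.csgraph`;
everything built on top of them is implemented here.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra, shortest_path

__all__ = [
    "WeightedGraph",
    "NetworkComplexityReport",
    "shortest_path_matrix",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "assortativity",
    "characteristic_path_length",
    "complexity_report",
]


@dataclass
class WeightedGraph:
    """Abstract weighted graph: edge index pairs plus lengths, no geometry.

    Null-model surrogates lose their spatial embedding, so metric routines
    accept either this or a :class:`~pknet.network.CenterlineGraph` (both
    expose ``n_nodes`` / ``edges`` / ``lengths``).
    """

    n_nodes: int
    edges: np.ndarray
    lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.lengths is None:
            self.lengths = np.ones(len(self.edges))
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(-1)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges.ravel(), 1)
        return deg


def _edge_lengths(graph, mode: str) -> np.ndarray:
    if mode == "binary":
        return np.ones(graph.n_edges)
    if mode == "weighted":
        return np.asarray(graph.lengths, dtype=float)
    raise ValueError(f"unknown metric mode {mode!r}")


def _distance_matrix(n: int, edges: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    if len(edges) == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    a, b = edges[:, 0], edges[:, 1]
    mat = csr_matrix(
        (np.concatenate([lengths, lengths]), (np.concatenate([a, b]), np.concatenate([b, a]))),
        shape=(n, n),
    )
    return dijkstra(mat, directed=False)


def shortest_path_matrix(graph, mode: str = "weighted") -> np.ndarray:
    """All-pairs geodesic distances; unreachable pairs are +inf, diagonal 0."""
    return _distance_matrix(graph.n_nodes, graph.edges, _edge_lengths(graph, mode))


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(graph, mode: str = "weighted") -> float:
    """Mean of 1/d(i, j) over ordered pairs i != j (1/inf = 0)."""
    if graph.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _efficiency_from_distances(shortest_path_matrix(graph, mode))


def local_efficiency(graph, mode: str = "weighted") -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean over all nodes.

    Node i's value is the global efficiency of the subgraph induced by its
    neighbours (paths may not leave that subgraph); nodes with fewer than two
    neighbours score 0.
    """
    if mode == "binary":
        return _local_efficiency_binary(graph)
    n = graph.n_nodes
    lengths = _edge_lengths(graph, mode)
    neighbours: list[list[int]] = [[] for _ in range(n)]
    weight: dict[tuple[int, int], float] = {}
    for (a, b), w in zip(graph.edges, lengths):
        a, b = int(a), int(b)
        neighbours[a].append(b)
        neighbours[b].append(a)
        weight[(a, b)] = weight[(b, a)] = w
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = neighbours[i]
        k = len(nbrs)
        if k < 2:
            continue
        sub = np.zeros((k, k))
        for p in range(k):
            for q in range(p + 1, k):
                w = weight.get((nbrs[p], nbrs[q]))
                if w is not None:
                    sub[p, q] = sub[q, p] = w
        dist = shortest_path(sub, method="D", directed=False)
        per_node[i] = _efficiency_from_distances(dist)
    return per_node, float(per_node.mean()) if n else 0.0


def _local_efficiency_binary(graph) -> tuple[np.ndarray, float]:
    # hop-count BFS on dense neighbour submatrices: much faster than a
    # Dijkstra call per node when nulls evaluate thousands of surrogates
    n = graph.n_nodes
    adjacency = np.zeros((n, n), dtype=bool)
    if graph.n_edges:
        adjacency[graph.edges[:, 0], graph.edges[:, 1]] = True
        adjacency |= adjacency.T
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adjacency[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = adjacency[np.ix_(nbrs, nbrs)]
        dist = np.where(sub, 1.0, np.inf)
        np.fill_diagonal(dist, 0.0)
        reach = sub | np.eye(k, dtype=bool)
        adj8 = sub.astype(np.uint8)
        d = 1
        while True:
            nreach = (reach.astype(np.uint8) @ adj8) > 0
            nreach |= reach
            new = nreach & ~reach
            if not new.any():
                break
            d += 1
            dist[new] = d
            reach = nreach
        per_node[i] = _efficiency_from_distances(dist)
    return per_node, float(per_node.mean()) if n else 0.0


def betweenness(graph, mode: str = "weighted") -> np.ndarray:
    """Normalised node betweenness in [0, 1] (Brandes, fractional counting).

    Raw pair dependencies are divided by (n-1)(n-2)/2, the number of ordered
    source/target pairs a node can intermediate in an undirected graph.
    """
    n = graph.n_nodes
    bc = np.zeros(n)
    if n < 3:
        return bc
    lengths = _edge_lengths(graph, mode)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (a, b), w in zip(graph.edges, lengths):
        adj[int(a)].append((int(b), float(w)))
        adj[int(b)].append((int(a), float(w)))
    for s in range(n):
        # Dijkstra building the shortest-path predecessor DAG; float distances
        # tie only when path sums are bitwise equal, the usual convention
        settled = np.zeros(n, dtype=bool)
        seen = {s: 0.0}
        pred: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if settled[v] or d > seen[v]:
                continue
            settled[v] = True
            order.append(v)
            for w, length in adj[v]:
                if settled[w]:
                    continue
                vw = d + length
                if w not in seen or vw < seen[w]:
                    seen[w] = vw
                    pred[w] = [v]
                    heapq.heappush(heap, (vw, w))
                elif vw == seen[w] and v not in pred[w]:
                    pred[w].append(v)
        # path counts in settled order, then dependency accumulation in reverse
        sigma = np.zeros(n)
        sigma[s] = 1.0
        for v in order[1:]:
            sigma[v] = sum(sigma[u] for u in pred[v])
        delta = np.zeros(n)
        for v in reversed(order):
            if v == s:
                continue
            coeff = (1.0 + delta[v]) / sigma[v]
            for u in pred[v]:
                delta[u] += sigma[u] * coeff
            bc[v] += delta[v]
    # each unordered pair was counted from both endpoints
    bc /= 2.0
    return bc / ((n - 1) * (n - 2) / 2.0)


def betweenness_histogram(values: np.ndarray, bins: int = 10) -> dict:
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return {"counts": counts.tolist(), "edges": edges.tolist()}


def assortativity(graph) -> float:
    """Degree assortativity: Pearson r of endpoint degrees over edges.

    Each undirected edge contributes its degree pair in both orientations.
    Returns NaN (undefined) when the endpoint-degree variance is zero, e.g.
    on a ring.  Raises on an edgeless graph.
    """
    if graph.n_edges == 0:
        raise ValueError("assortativity undefined for an edgeless graph")
    deg = graph.degrees()
    x = np.concatenate([deg[graph.edges[:, 0]], deg[graph.edges[:, 1]]]).astype(float)
    y = np.concatenate([deg[graph.edges[:, 1]], deg[graph.edges[:, 0]]]).astype(float)
    vx = x.var()
    if vx == 0.0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def characteristic_path_length(graph, mode: str = "weighted") -> tuple[float, int]:
    """Mean finite shortest-path length over ordered pairs i != j.

    Returns ``(mean, n_unreachable_ordered_pairs)``; unreachable pairs are
    excluded from the mean and counted separately.  Raises if every pair is
    unreachable.
    """
    if graph.n_nodes < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    dist = shortest_path_matrix(graph, mode)
    off = ~np.eye(graph.n_nodes, dtype=bool)
    finite = np.isfinite(dist) & off
    n_inf = int(np.count_nonzero(off) - np.count_nonzero(finite))
    if not finite.any():
        raise ValueError("all node pairs unreachable")
    return float(dist[finite].mean()), n_inf


@dataclass
class NetworkComplexityReport:
    """Per-network complexity summary (Fig-7-style panel values)."""

    mode: str
    n_nodes: int
    n_edges: int
    global_efficiency: float
    local_efficiency_mean: float
    local_efficiency: np.ndarray
    characteristic_path_length: float
    n_unreachable_pairs: int
    degree: np.ndarray
    betweenness: np.ndarray
    betweenness_hist: dict
    assortativity: float

    @property
    def assortativity_defined(self) -> bool:
        return not math.isnan(self.assortativity)

    def to_dict(self) -> dict:
        """JSON-ready dict keyed by the conventional panel abbreviations."""
        return {
            "mode": self.mode,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "G.E": self.global_efficiency,
            "L.E": self.local_efficiency_mean,
            "C.P.Length": self.characteristic_path_length,
            "unreachable_pairs": self.n_unreachable_pairs,
            "Degree": self.degree.tolist(),
            "Degree.mean": float(self.degree.mean()),
            "Betweenness": self.betweenness.tolist(),
            "Betweenness.hist": self.betweenness_hist,
            "Assort": None if not self.assortativity_defined else self.assortativity,
        }


def complexity_report(graph, mode: str = "weighted") -> NetworkComplexityReport:
    """Compute the full metric panel for one network."""
    per_node_le, mean_le = local_efficiency(graph, mode)
    cpl, n_inf = characteristic_path_length(graph, mode)
    bc = betweenness(graph, mode)
    try:
        assort = assortativity(graph)
    except ValueError:
        assort = float("nan")
    return NetworkComplexityReport(
        mode=mode,
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        global_efficiency=global_efficiency(graph, mode),
        local_efficiency_mean=mean_le,
        local_efficiency=per_node_le,
        characteristic_path_length=cpl,
        n_unreachable_pairs=n_inf,
        degree=graph.degrees(),
        betweenness=bc,
        betweenness_hist=betweenness_histogram(bc),
        assortativity=assort,
    )
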