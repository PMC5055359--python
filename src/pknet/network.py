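"""Centreline-network reconstruction: spatial graph, branches, furcation angles.

The centreline graph is a spatially embedded undirected graph: nodes are
landmarks (furcations, pathway waypoints, terminals), edges are straight
segments with Euclidean length in um.  Branches are maximal chains of edges
between nodes of degree != 2 — the runs of connected cells without any
furcation.  At each furcation the angle between every unordered pair of
incident outward unit vectors is reported and classified acute (alpha, < 90
degrees) or obtuse (beta, >= 90 degrees); a degree-3 'Y' yields one alpha and
two betas when branches diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LandmarkSet

__all__ = [
    "CenterlineGraph",
    "BranchSet",
    "Branch",
    "FurcationAngle",
    "GraphBuildError",
    "build_graph",
    "extract_branches",
    "furcation_angles",
    "branch_stats",
]


class GraphBuildError(ValueError):
    """Invalid centreline topology (self-loop, duplicate or zero-length edge)."""


@dataclass
class CenterlineGraph:
    """Spatially embedded undirected graph of fibre centrelines.

    ``positions`` is (n, 3) in um; ``edges`` is (m, 2) node indices with
    a < b; ``lengths`` the Euclidean edge lengths.  ``ids`` keeps landmark
    names for reporting.
    """

    positions: np.ndarray
    edges: np.ndarray
    ids: list[str] = field(default_factory=list)
    lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            self.edges = np.sort(self.edges, axis=1)
        if not self.ids:
            self.ids = [f"N{i}" for i in range(len(self.positions))]
        if self.lengths is None:
            if self.edges.size:
                diff = self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]
                self.lengths = np.linalg.norm(diff, axis=1)
            else:
                self.lengths = np.empty(0)
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(-1)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def node_role(self, node: int) -> str:
        d = self.degrees()[node]
        if d <= 1:
            return "terminal"
        if d == 2:
            return "pass_through"
        return "furcation"

    def adjacency(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_nodes)]
        for (a, b), w in zip(self.edges, self.lengths):
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def connected_components(self) -> np.ndarray:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = self.n_nodes
        if self.n_edges == 0:
            return np.arange(n)
        a, b = self.edges[:, 0], self.edges[:, 1]
        mat = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
        return connected_components(mat, directed=False)[1]


def build_graph(landmarks: LandmarkSet, edge_list: list[tuple[str, str]]) -> CenterlineGraph:
    """Connect landmarks with straight segments to form the centreline graph.

    Raises :class:`GraphBuildError` naming the edge for self-loops, duplicate
    edges, unknown ids, or zero-length edges.
    """
    index = {lid: i for i, lid in enumerate(landmarks.ids)}
    edges = []
    seen: set[tuple[int, int]] = set()
    for a_id, b_id in edge_list:
        if a_id not in index:
            raise GraphBuildError(f"edge references unknown landmark {a_id!r}")
        if b_id not in index:
            raise GraphBuildError(f"edge references unknown landmark {b_id!r}")
        if a_id == b_id:
            raise GraphBuildError(f"self-loop {a_id}–{b_id}")
        a, b = sorted((index[a_id], index[b_id]))
        if (a, b) in seen:
            raise GraphBuildError(f"duplicate edge {a_id}–{b_id}")
        seen.add((a, b))
        if np.linalg.norm(landmarks.xyz[a] - landmarks.xyz[b]) == 0.0:
            raise GraphBuildError(f"zero-length edge {a_id}–{b_id}")
        edges.append((a, b))
    return CenterlineGraph(
        positions=landmarks.xyz.copy(),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        ids=list(landmarks.ids),
    )


@dataclass
class Branch:
    """Maximal furcation-free chain: node-index path and its length in um."""

    nodes: list[int]
    length: float
    closed: bool = False  # pure cycle of degree-2 nodes


@dataclass
class BranchSet:
    branches: list[Branch]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([b.length for b in self.branches], dtype=float)

    def __len__(self) -> int:
        return len(self.branches)


def extract_branches(graph: CenterlineGraph) -> BranchSet:
    """Split the graph into maximal chains between degree != 2 nodes.

    Interior nodes of a branch have degree 2; endpoints do not.  Components
    that are pure cycles of degree-2 nodes come out as one closed branch.
    """
    deg = graph.degrees()
    adj = graph.adjacency()
    edge_index = {tuple(e): k for k, e in enumerate(map(tuple, graph.edges))}
    visited = np.zeros(graph.n_edges, dtype=bool)
    branches: list[Branch] = []

    def walk(start: int, first: int) -> Branch:
        """Follow degree-2 nodes from `start` through neighbour `first`."""
        path = [start, first]
        k = edge_index[tuple(sorted((start, first)))]
        visited[k] = True
        length = graph.lengths[k]
        prev, cur = start, first
        while deg[cur] == 2:
            nxt = next(n for n, _ in adj[cur] if n != prev)
            k = edge_index[tuple(sorted((cur, nxt)))]
            if visited[k]:
                break
            visited[k] = True
            length += graph.lengths[k]
            path.append(nxt)
            prev, cur = cur, nxt
        return Branch(path, float(length))

    for node in range(graph.n_nodes):
        if deg[node] == 2:
            continue
        for nbr, _ in adj[node]:
            k = edge_index[tuple(sorted((node, nbr)))]
            if not visited[k]:
                branches.append(walk(node, nbr))

    # remaining unvisited edges belong to pure degree-2 cycles
    for k in range(graph.n_edges):
        if not visited[k]:
            a = int(graph.edges[k, 0])
            b = int(graph.edges[k, 1])
            branch = walk(a, b)
            # close the loop: walk stops when it returns to the start edge
            branch.closed = True
            if branch.nodes[-1] != a:
                kk = edge_index[tuple(sorted((branch.nodes[-1], a)))]
                if not visited[kk]:
                    visited[kk] = True
                    branch.length += float(graph.lengths[kk])
                    branch.nodes.append(a)
            branches.append(branch)
    return BranchSet(branches)


@dataclass
class FurcationAngle:
    node: int
    neighbours: tuple[int, int]
    angle_deg: float
    population: str  # "alpha" (< 90) or "beta" (>= 90)


def furcation_angles(graph: CenterlineGraph) -> list[FurcationAngle]:
    """Angles between all pairs of incident segments at furcation nodes.

    Uses the immediate outward unit vectors node -> adjacent landmark; a
    degree-3 node yields C(3,2) = 3 angles.  Exactly 90 degrees classifies
    as beta (the acute population is the open interval below 90).
    """
    deg = graph.degrees()
    adj = graph.adjacency()
    out: list[FurcationAngle] = []
    for node in range(graph.n_nodes):
        if deg[node] < 3:
            continue
        nbrs = sorted(n for n, _ in adj[node])
        vecs = {}
        for n in nbrs:
            v = graph.positions[n] - graph.positions[node]
            norm = np.linalg.norm(v)
            if norm == 0.0:
                raise GraphBuildError(
                    f"coincident landmarks at furcation {graph.ids[node]!r}"
                )
            vecs[n] = v / norm
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1:]:
                cosang = float(np.clip(np.dot(vecs[a], vecs[b]), -1.0, 1.0))
                ang = float(np.degrees(np.arccos(cosang)))
                out.append(
                    FurcationAngle(
                        node=node,
                        neighbours=(a, b),
                        angle_deg=ang,
                        population="alpha" if ang < 90.0 else "beta",
                    )
                )
    return out


def branch_stats(
    branches: BranchSet, bin_width: float = 25.0
) -> dict:
    """Mean/median branch length and a fixed-width histogram (default 25 um)."""
    if len(branches) == 0:
        raise ValueError("no branches")
    lengths = branches.lengths
    upper = max(300.0, float(np.ceil(lengths.max() / bin_width) * bin_width))
    bins = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, edges = np.histogram(lengths, bins=bins)
    return {
        "n": int(len(lengths)),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": float(lengths.min()),
        "max": float(lengths.max()),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }
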