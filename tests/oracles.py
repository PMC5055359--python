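"""Independent brute-force oracles used only by the test suite.

Everything here deliberately avoids the implementation under test: shortest
paths by exhaustive simple-path enumeration, efficiencies/betweenness by
direct application of their definitions to the enumerated paths, degree
assortativity as a plain Pearson correlation, and mesh volume by counting
voxel centres inside the surface via ray-crossing parity.
"""

from __future__ import annotations

import numpy as np


def _adjacency(n: int, edges, lengths) -> list[list[tuple[int, float]]]:
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (a, b), w in zip(edges, lengths):
        adj[int(a)].append((int(b), float(w)))
        adj[int(b)].append((int(a), float(w)))
    return adj


def enumerate_simple_paths(n, edges, lengths, s, t):
    """All simple paths s->t as (length, node tuple), length summed from s."""
    adj = _adjacency(n, edges, lengths)
    out = []

    def dfs(v, visited, dist, path):
        if v == t:
            out.append((dist, tuple(path)))
            return
        for w, wlen in adj[v]:
            if w not in visited:
                visited.add(w)
                path.append(w)
                dfs(w, visited, dist + wlen, path)
                path.pop()
                visited.remove(w)

    dfs(s, {s}, 0.0, [s])
    return out


def brute_distance_matrix(n, edges, lengths) -> np.ndarray:
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(n, edges, lengths, s, t)
            if paths:
                best = min(p[0] for p in paths)
                dist[s, t] = dist[t, s] = best
    return dist


def brute_global_efficiency(n, edges, lengths) -> float:
    dist = brute_distance_matrix(n, edges, lengths)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(n, edges, lengths) -> float:
    adj = _adjacency(n, edges, lengths)
    per = np.zeros(n)
    for i in range(n):
        nbrs = sorted(w for w, _ in adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        remap = {v: idx for idx, v in enumerate(nbrs)}
        sub_edges, sub_lengths = [], []
        for (a, b), w in zip(edges, lengths):
            if int(a) in remap and int(b) in remap:
                sub_edges.append((remap[int(a)], remap[int(b)]))
                sub_lengths.append(w)
        per[i] = brute_global_efficiency(k, sub_edges, sub_lengths)
    return float(per.mean())


def brute_betweenness(n, edges, lengths) -> np.ndarray:
    """Normalised betweenness by explicit enumeration of all shortest paths."""
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(n, edges, lengths, s, t)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            shortest = [p[1] for p in paths if p[0] == best]
            sigma = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for path in shortest if v in path)
                bc[v] += through / sigma
    return bc / ((n - 1) * (n - 2) / 2.0)


def brute_characteristic_path_length(n, edges, lengths) -> float:
    dist = brute_distance_matrix(n, edges, lengths)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    return float(dist[finite].mean())


def pearson_assortativity(n, edges) -> float:
    deg = np.zeros(n)
    for a, b in edges:
        deg[int(a)] += 1
        deg[int(b)] += 1
    x, y = [], []
    for a, b in edges:
        x += [deg[int(a)], deg[int(b)]]
        y += [deg[int(b)], deg[int(a)]]
    return float(np.corrcoef(x, y)[0, 1])


def voxel_volume(mesh, pitch: float = 0.31) -> float:
    """Volume as (count of voxel centres inside the surface) x pitch^3.

    A vertical ray is cast through each voxel column; triangle crossings are
    collected and voxel centres between consecutive crossing pairs counted.
    The grid is offset by an irrational-ish fraction of the pitch so rays
    passing exactly through mesh edges have measure zero.
    """
    v, f = mesh.vertices, mesh.faces
    lo, hi = v.min(axis=0), v.max(axis=0)
    eps = pitch * 0.5000127
    xs = np.arange(lo[0] + eps, hi[0], pitch)
    ys = np.arange(lo[1] + eps, hi[1], pitch)
    crossings: dict[tuple[int, int], list[float]] = {}
    tri = v[f]
    for t in tri:
        x0, x1 = t[:, 0].min(), t[:, 0].max()
        y0, y1 = t[:, 1].min(), t[:, 1].max()
        xi = np.flatnonzero((xs >= x0) & (xs <= x1))
        yi = np.flatnonzero((ys >= y0) & (ys <= y1))
        if xi.size == 0 or yi.size == 0:
            continue
        gx, gy = np.meshgrid(xs[xi], ys[yi], indexing="ij")
        px = gx.ravel()
        py = gy.ravel()
        a2, b2, c2 = t[0, :2], t[1, :2], t[2, :2]
        det = (b2[0] - a2[0]) * (c2[1] - a2[1]) - (b2[1] - a2[1]) * (c2[0] - a2[0])
        if det == 0.0:
            continue
        w1 = ((px - a2[0]) * (c2[1] - a2[1]) - (py - a2[1]) * (c2[0] - a2[0])) / det
        w2 = ((b2[0] - a2[0]) * (py - a2[1]) - (b2[1] - a2[1]) * (px - a2[0])) / det
        inside = (w1 > 0) & (w2 > 0) & (w1 + w2 < 1)
        if not inside.any():
            continue
        z = t[0, 2] + w1[inside] * (t[1, 2] - t[0, 2]) + w2[inside] * (t[2, 2] - t[0, 2])
        kk = np.flatnonzero(inside)
        for pos, zval in zip(kk, z):
            key = (int(xi[pos // yi.size]), int(yi[pos % yi.size]))
            crossings.setdefault(key, []).append(float(zval))
    z0 = lo[2] + eps
    count = 0
    for zlist in crossings.values():
        zlist.sort()
        if len(zlist) % 2:
            continue  # grazing column: parity broken, skip (measure ~0)
        for lo_z, hi_z in zip(zlist[::2], zlist[1::2]):
            k_lo = int(np.ceil((lo_z - z0) / pitch))
            k_hi = int(np.floor((hi_z - z0) / pitch))
            if (z0 + k_lo * pitch) < lo_z:
                k_lo += 1
            count += max(0, k_hi - k_lo + 1)
    return count * pitch**3
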