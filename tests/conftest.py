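import numpy as np
import pytest
from hypothesis import settings

from pknet.io_formats import TriMesh
from pknet.network import CenterlineGraph

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def graph_from(positions, edges) -> CenterlineGraph:
    return CenterlineGraph(positions=np.asarray(positions, float),
                           edges=np.asarray(edges, int).reshape(-1, 2))


@pytest.fixture
def unit_cube() -> TriMesh:
    """Axis-aligned unit cube, outward-oriented (area 6, volume 1)."""
    vertices = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    faces = np.array(
        [[0, 2, 1], [0, 3, 2],      # bottom (z=0), normal -z
         [4, 5, 6], [4, 6, 7],      # top (z=1), normal +z
         [0, 1, 5], [0, 5, 4],      # y=0 side
         [1, 2, 6], [1, 6, 5],      # x=1 side
         [2, 3, 7], [2, 7, 6],      # y=1 side
         [3, 0, 4], [3, 4, 7]]      # x=0 side
    )
    return TriMesh(vertices, faces)


@pytest.fixture
def right_tetrahedron() -> TriMesh:
    """Corner tetrahedron (0,0,0),(1,0,0),(0,1,0),(0,0,1); volume 1/6."""
    vertices = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(vertices, faces)


@pytest.fixture
def regular_tetrahedron() -> TriMesh:
    """Regular tetrahedron with unit edge (area sqrt(3))."""
    vertices = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(8)  # edge length 1
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriMesh(vertices, faces)


@pytest.fixture
def y_graph() -> CenterlineGraph:
    """Hub at origin with three 50 um arms at 120 degrees in the plane."""
    arms = [np.array([np.cos(a), np.sin(a), 0.0]) * 50.0
            for a in np.radians([0, 120, 240])]
    return graph_from([[0, 0, 0]] + [a.tolist() for a in arms],
                      [[0, 1], [0, 2], [0, 3]])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_connected_graph(rng: np.random.Generator, n: int, extra_edges: int = 3):
    """Random spanning tree plus a few extra edges, with random weights."""
    edges = set()
    for v in range(1, n):
        edges.add((int(rng.integers(v)), v))
    attempts = 0
    while len(edges) < n - 1 + extra_edges and attempts < 50:
        attempts += 1
        a, b = sorted(rng.choice(n, size=2, replace=False).tolist())
        edges.add((a, b))
    edges = np.array(sorted(edges))
    weights = rng.uniform(0.5, 3.0, size=len(edges))
    return edges, weights
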