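"""Reading and writing landmark files, edge lists, and triangle meshes.

Landmarks use a fiducial-style CSV dialect: one labelled 3D point per row
(``id,x,y,z,label``), coordinates in micrometres, ``#`` comment lines allowed.
A comment header line of the form ``# CoordinateSystem: RAS`` (or ``LPS``)
declares the anatomical frame; LPS input is converted to RAS on read by
negating x and y.  Connectivity is a separate two-column id file, because
landmark exports carry no topology.

Meshes are closed oriented triangle surfaces (PLY / STL / OBJ).  trimesh backs
parsing; PLY is written by a small binary little-endian float64 writer so that
coordinates survive a write/read roundtrip to 1e-6 um even at field-of-view
scale (~300 um), where float32 would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "LandmarkSet",
    "TriMesh",
    "LandmarkError",
    "MeshTopologyError",
    "read_landmarks",
    "write_landmarks",
    "read_edge_list",
    "write_edge_list",
    "read_mesh",
    "write_mesh",
]

#: Confocal voxel pitch in um; default minimum landmark separation.
VOXEL_SIZE_UM = 0.31


class LandmarkError(ValueError):
    """Malformed landmark or edge-list input."""


class MeshTopologyError(ValueError):
    """Mesh violates the closed-oriented-surface contract."""


@dataclass
class LandmarkSet:
    """Labelled 3D points (um) defining network waypoints.

    ``ids`` are unique strings; ``xyz`` is an (n, 3) float64 array in the RAS
    frame after reading.
    """

    ids: list[str]
    xyz: np.ndarray
    labels: list[str] = field(default_factory=list)
    stack_id: str = ""
    frame: str = "RAS"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if len(self.ids) != len(self.xyz):
            raise LandmarkError("ids and coordinates differ in length")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise LandmarkError(f"duplicate landmark id {dup!r}")
        if not np.all(np.isfinite(self.xyz)):
            raise LandmarkError("non-finite landmark coordinates")
        if self.frame not in ("RAS", "LPS"):
            raise LandmarkError(f"unknown coordinate frame {self.frame!r}")
        if not self.labels:
            self.labels = [""] * len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, landmark_id: str) -> int:
        return self.ids.index(landmark_id)

    def validate_separation(self, tolerance: float = VOXEL_SIZE_UM) -> None:
        """Raise if any two points are closer than ``tolerance`` um (one voxel)."""
        if len(self) < 2:
            return
        tree = cKDTree(self.xyz)
        pairs = tree.query_pairs(tolerance)
        if pairs:
            i, j = sorted(pairs)[0]
            raise LandmarkError(
                f"landmarks {self.ids[i]!r} and {self.ids[j]!r} are closer "
                f"than the merge tolerance ({tolerance} um)"
            )

    def to_frame(self, frame: str) -> "LandmarkSet":
        """Return a copy in the requested frame (RAS<->LPS negates x and y)."""
        if frame not in ("RAS", "LPS"):
            raise LandmarkError(f"unknown coordinate frame {frame!r}")
        xyz = self.xyz.copy()
        if frame != self.frame:
            xyz[:, :2] *= -1.0
        return LandmarkSet(list(self.ids), xyz, list(self.labels), self.stack_id, frame)


def read_landmarks(
    path: str | Path,
    frame_override: str | None = None,
    merge_tolerance: float = VOXEL_SIZE_UM,
) -> LandmarkSet:
    """Parse a fiducial CSV into a :class:`LandmarkSet` in the RAS frame.

    The frame comes from a ``# CoordinateSystem:`` header comment unless
    ``frame_override`` is given.  Raises :class:`LandmarkError` naming the
    offending line for duplicate ids, non-numeric coordinates, or an unknown
    frame.
    """
    path = Path(path)
    frame = frame_override
    stack_id = path.stem
    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, value = body.partition(":")
                if key.strip().lower() == "coordinatesystem" and frame_override is None:
                    frame = value.strip().upper()
                elif key.strip().lower() == "stack_id":
                    stack_id = value.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 4:
                raise LandmarkError(f"line {lineno}: expected id,x,y,z[,label]")
            if parts[0] in ids:
                raise LandmarkError(f"line {lineno}: duplicate landmark id {parts[0]!r}")
            try:
                coords = [float(v) for v in parts[1:4]]
            except ValueError:
                raise LandmarkError(
                    f"line {lineno}: non-numeric coordinate in {parts[1:4]!r}"
                ) from None
            ids.append(parts[0])
            rows.append(coords)
            labels.append(parts[4] if len(parts) > 4 else "")
    if frame is None:
        raise LandmarkError(f"{path}: no CoordinateSystem header and no frame override")
    frame = frame.upper()
    if frame not in ("RAS", "LPS"):
        raise LandmarkError(f"{path}: unknown coordinate frame {frame!r}")
    lm = LandmarkSet(ids, np.array(rows, dtype=float).reshape(-1, 3), labels, stack_id, frame)
    if frame == "LPS":
        lm = lm.to_frame("RAS")
    lm.validate_separation(merge_tolerance)
    return lm


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stack_id: {landmarks.stack_id}\n")
        fh.write(f"# CoordinateSystem: {landmarks.frame}\n")
        fh.write("# columns: id,x,y,z,label\n")
        for i, lid in enumerate(landmarks.ids):
            x, y, z = (float(v) for v in landmarks.xyz[i])
            fh.write(f"{lid},{x!r},{y!r},{z!r},{landmarks.labels[i]}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column (tab or comma separated) id file; '#' comments ignored."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise LandmarkError(f"line {lineno}: expected two landmark ids")
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: id_a\tid_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Triangle meshes


@dataclass
class TriMesh:
    """Closed, consistently oriented triangle surface (coordinates in um)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshTopologyError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def boundary_edge_count(self) -> int:
        """Number of undirected edges not shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.count_nonzero(counts != 2))

    def is_watertight(self) -> bool:
        return self.boundary_edge_count() == 0

    def is_consistently_oriented(self) -> bool:
        """True when every directed edge occurs exactly once (coherent winding)."""
        directed = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        _, counts = np.unique(directed, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def validate_closed(mesh: TriMesh) -> None:
    """Raise :class:`MeshTopologyError` (reporting the boundary-edge count) if open."""
    n_boundary = mesh.boundary_edge_count()
    if n_boundary:
        raise MeshTopologyError(f"open surface: {n_boundary} boundary edges")


def orient_outward(mesh: TriMesh) -> TriMesh:
    """Flip all faces if the signed (divergence-theorem) volume is negative."""
    from .morphometry import signed_volume

    if signed_volume(mesh) < 0:
        return TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def read_mesh(path: str | Path) -> TriMesh:
    """Load a PLY/STL/OBJ mesh, validate closure, and orient it outward.

    STL files duplicate vertices per facet; they are merged on read by exact
    coordinate hashing.  Open or non-manifold surfaces raise
    :class:`MeshTopologyError` with the boundary-edge count.
    """
    path = Path(path)
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in ("ply", "stl", "obj"):
        raise ValueError(f"unsupported mesh format {suffix!r}")
    loaded = trimesh.load(str(path), file_type=suffix, process=False)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if len(geoms) != 1:
            raise MeshTopologyError(f"{path}: expected a single mesh, got {len(geoms)}")
        loaded = geoms[0]
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if suffix == "stl":
        vertices, faces = _merge_duplicate_vertices(vertices, faces)
    mesh = TriMesh(vertices, faces)
    validate_closed(mesh)
    return orient_outward(mesh)


def _merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    # exact-bit hashing: STL stores each facet's corners verbatim, so shared
    # corners are bitwise equal and float tolerance is unnecessary
    unique, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return unique, inverse[faces]


def write_mesh(mesh: TriMesh, path: str | Path, file_format: str | None = None) -> None:
    """Write PLY (binary little-endian float64, default), STL, or OBJ."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply_double(mesh, path)
    elif fmt in ("stl", "obj"):
        mesh.to_trimesh().export(str(path), file_type=fmt)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def _write_ply_double(mesh: TriMesh, path: Path) -> None:
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    face_dtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
    face_block = np.empty(mesh.n_faces, dtype=face_dtype)
    face_block["n"] = 3
    face_block["idx"] = mesh.faces.astype("<i4")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(mesh.vertices.astype("<f8").tobytes())
        fh.write(face_block.tobytes())
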