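"""Triangle meshes, rigid transforms, validation, and the interpenetration
test that defines pose viability.

Geometry is in millimetres throughout; angles are degrees.  Meshes used for
collision testing must be watertight (every edge shared by exactly two faces)
and consistently wound so that the ray-parity containment test is defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _collision
from .errors import MeshError, MeshParseError

__all__ = [
    "TriMesh",
    "RigidTransform",
    "MeshReport",
    "load_mesh",
    "save_mesh",
    "validate_mesh",
    "transform_mesh",
    "meshes_intersect",
]

#: Factor applied to coordinates on load to normalize them to millimetres.
UNIT_SCALES = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclass
class TriMesh:
    """Indexed triangle surface mesh in a local frame (mm units)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"{self.name}: vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"{self.name}: faces must be (m, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError(f"{self.name}: face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] vertex coordinates."""
        return np.vstack([self.vertices.min(0), self.vertices.max(0)])

    def extent_along(self, direction) -> float:
        """Width of the vertex cloud along a (not necessarily unit) axis."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        proj = self.vertices @ d
        return float(proj.max() - proj.min())

    def copy(self, name: str | None = None) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(), self.faces.copy(), name or self.name
        )


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform v' = scale * R @ v + t (scale defaults to 1)."""

    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=np.float64)
        )
        object.__setattr__(
            self, "translation",
            np.asarray(self.translation, dtype=np.float64).reshape(3),
        )
        r = self.rotation
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation determinant must be +1")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(v) = self(other(v))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(
            rt, -(rt @ self.translation) / self.scale, 1.0 / self.scale
        )


@dataclass(frozen=True)
class MeshReport:
    """Deterministic cleanliness audit of a mesh."""

    watertight: bool
    manifold: bool
    self_intersecting: bool
    consistent_normals: bool
    n_vertices: int
    n_faces: int
    n_components: int

    @property
    def clean(self) -> bool:
        """The alpha-shape cleanliness requirement: manifold, consistently
        wound, free of self-intersections (and closed)."""
        return (
            self.watertight
            and self.manifold
            and self.consistent_normals
            and not self.self_intersecting
        )


def _edge_maps(faces: np.ndarray):
    undirected: dict[tuple[int, int], int] = {}
    directed: dict[tuple[int, int], int] = {}
    for f in faces:
        a, b, c = int(f[0]), int(f[1]), int(f[2])
        for u, v in ((a, b), (b, c), (c, a)):
            directed[(u, v)] = directed.get((u, v), 0) + 1
            key = (u, v) if u < v else (v, u)
            undirected[key] = undirected.get(key, 0) + 1
    return undirected, directed


def validate_mesh(mesh: TriMesh) -> MeshReport:
    """Audit watertightness, manifoldness, winding and self-intersection.

    Degenerate meshes produce flags, never exceptions.  ``manifold`` here is
    edge-manifoldness (every edge borders at most two faces), so watertight
    (exactly two everywhere) implies manifold.
    """
    faces = mesh.faces
    if len(faces) == 0:
        return MeshReport(False, False, False, False, mesh.n_vertices, 0, 0)
    undirected, directed = _edge_maps(faces)
    counts = np.fromiter(undirected.values(), dtype=np.int64)
    watertight = bool((counts == 2).all())
    manifold = bool((counts <= 2).all())
    consistent = all(v == 1 for v in directed.values())
    selfx = bool(
        _collision.self_intersects(mesh.vertices, mesh.faces)
    )
    # face connectivity components via union-find over shared edges
    parent = np.arange(len(faces))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_faces: dict[tuple[int, int], int] = {}
    for fi, f in enumerate(faces):
        a, b, c = int(f[0]), int(f[1]), int(f[2])
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            if key in edge_faces:
                ra, rb = find(edge_faces[key]), find(fi)
                parent[ra] = rb
            else:
                edge_faces[key] = fi
    n_components = len({find(i) for i in range(len(faces))})
    return MeshReport(
        watertight=watertight,
        manifold=manifold,
        self_intersecting=selfx,
        consistent_normals=consistent,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_components=n_components,
    )


def transform_mesh(mesh: TriMesh, xf: RigidTransform) -> TriMesh:
    """Apply a rigid/similarity transform to every vertex; faces unchanged."""
    return TriMesh(xf.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


def _require_watertight(mesh: TriMesh) -> None:
    und, _ = _edge_maps(mesh.faces)
    if len(mesh.faces) == 0 or any(v != 2 for v in und.values()):
        raise MeshError(
            f"mesh '{mesh.name}' is not watertight; "
            "containment test undefined"
        )


def meshes_intersect(
    a: TriMesh,
    xf_a: RigidTransform,
    b: TriMesh,
    xf_b: RigidTransform,
) -> bool:
    """Strict interpenetration test between two posed watertight meshes.

    True iff a triangle of posed ``a`` properly crosses a triangle of posed
    ``b``, or one posed mesh lies entirely inside the other.  Exact surface
    tangency without crossing is NOT an intersection (the pose stays viable).
    """
    _require_watertight(a)
    _require_watertight(b)
    va = xf_a.apply(a.vertices)
    vb = xf_b.apply(b.vertices)
    if _collision.any_pair_intersects(va, a.faces, vb, b.faces):
        return True
    # zero surface crossings: either disjoint or one fully inside the other
    if _collision.point_in_mesh(va[0], vb, b.faces):
        return True
    if _collision.point_in_mesh(vb[0], va, a.faces):
        return True
    return False


# ---------------------------------------------------------------------------
# File formats: OBJ (reference dialect), ASCII STL, ASCII PLY
# ---------------------------------------------------------------------------

def _parse_fail(path, why: str) -> MeshParseError:
    return MeshParseError(f"parse failure in {path}: {why}")


def _load_obj(path: Path) -> TriMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise _parse_fail(path, str(exc)) from exc
    for ln, line in enumerate(text.splitlines(), 1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        try:
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
                if len(parts) < 4:
                    raise ValueError("short vertex record")
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                if len(idx) < 3:
                    raise ValueError("short face record")
                if any(i == 0 for i in idx):
                    raise ValueError("OBJ indices are 1-based")
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                    faces.append([idx[0], idx[k], idx[k + 1]])
        except ValueError as exc:
            raise _parse_fail(path, f"line {ln}: {exc}") from exc
    if not faces:
        raise _parse_fail(path, "no faces")
    return TriMesh(np.asarray(verts), np.asarray(faces), name=path.stem)


def _load_stl(path: Path) -> TriMesh:
    try:
        text = path.read_text()
    except (OSError, UnicodeDecodeError) as exc:
        raise _parse_fail(
            path, "unreadable or binary STL (only ASCII STL is supported)"
        ) from exc
    if not text.lstrip().lower().startswith("solid"):
        raise _parse_fail(path, "missing 'solid' header (binary STL?)")
    coords: list[tuple[float, float, float]] = []
    for ln, line in enumerate(text.splitlines(), 1):
        parts = line.split()
        if parts[:1] == ["vertex"]:
            try:
                coords.append(tuple(float(x) for x in parts[1:4]))
                if len(parts) < 4:
                    raise ValueError("short vertex record")
            except ValueError as exc:
                raise _parse_fail(path, f"line {ln}: {exc}") from exc
    if len(coords) == 0 or len(coords) % 3:
        raise _parse_fail(path, "vertex count not a multiple of 3")
    # merge exactly coincident vertices so topology is recoverable
    index: dict[tuple[float, float, float], int] = {}
    verts: list[tuple[float, float, float]] = []
    faces = []
    for i in range(0, len(coords), 3):
        tri = []
        for c in coords[i:i + 3]:
            if c not in index:
                index[c] = len(verts)
                verts.append(c)
            tri.append(index[c])
        faces.append(tri)
    return TriMesh(np.asarray(verts), np.asarray(faces), name=path.stem)


def _load_ply(path: Path) -> TriMesh:
    try:
        lines = path.read_text().splitlines()
    except (OSError, UnicodeDecodeError) as exc:
        raise _parse_fail(path, "unreadable or non-ASCII PLY") from exc
    if not lines or lines[0].strip() != "ply":
        raise _parse_fail(path, "missing 'ply' magic")
    n_vert = n_face = None
    i = 1
    order: list[tuple[str, int]] = []
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise _parse_fail(path, "only ASCII PLY is supported")
        if parts[0] == "element":
            order.append((parts[1], int(parts[2])))
            if parts[1] == "vertex":
                n_vert = int(parts[2])
            elif parts[1] == "face":
                n_face = int(parts[2])
        if parts[0] == "end_header":
            break
    else:
        raise _parse_fail(path, "missing end_header")
    if n_vert is None or n_face is None:
        raise _parse_fail(path, "missing vertex or face element")
    body = [ln.split() for ln in lines[i:] if ln.strip()]
    if len(body) < n_vert + n_face:
        raise _parse_fail(path, "truncated body")
    try:
        verts = np.asarray(
            [[float(x) for x in row[:3]] for row in body[:n_vert]]
        )
        faces = []
        for row in body[n_vert:n_vert + n_face]:
            k = int(row[0])
            idx = [int(x) for x in row[1:1 + k]]
            for j in range(1, k - 1):
                faces.append([idx[0], idx[j], idx[j + 1]])
    except (ValueError, IndexError) as exc:
        raise _parse_fail(path, str(exc)) from exc
    if not faces:
        raise _parse_fail(path, "no faces")
    return TriMesh(verts, np.asarray(faces), name=path.stem)


_LOADERS = {"obj": _load_obj, "stl": _load_stl, "ply": _load_ply}


def load_mesh(
    path, file_format: str | None = None, units: str = "mm"
) -> TriMesh:
    """Load an OBJ/ASCII-STL/ASCII-PLY mesh, normalizing units to mm."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _LOADERS:
        raise MeshParseError(f"unsupported mesh format: {fmt!r}")
    if units not in UNIT_SCALES:
        raise ValueError(f"unknown units {units!r}")
    mesh = _LOADERS[fmt](path)
    if UNIT_SCALES[units] != 1.0:
        mesh = TriMesh(
            mesh.vertices * UNIT_SCALES[units], mesh.faces, mesh.name
        )
    return mesh


def save_mesh(mesh: TriMesh, path, file_format: str | None = None) -> Path:
    """Write a mesh as OBJ (1-based ``v``/``f``), ASCII STL, or ASCII PLY."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    out: list[str] = []
    if fmt == "obj":
        for v in mesh.vertices:
            out.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        for f in mesh.faces:
            out.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    elif fmt == "stl":
        out.append(f"solid {mesh.name}")
        for f in mesh.faces:
            a, b, c = (mesh.vertices[i] for i in f)
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            out.append(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
            out.append("    outer loop")
            for v in (a, b, c):
                out.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            out.append("    endloop")
            out.append("  endfacet")
        out.append(f"endsolid {mesh.name}")
    elif fmt == "ply":
        out += [
            "ply", "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property float x", "property float y", "property float z",
            f"element face {mesh.n_faces}",
            "property list uchar int vertex_indices", "end_header",
        ]
        for v in mesh.vertices:
            out.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        for f in mesh.faces:
            out.append(f"3 {f[0]} {f[1]} {f[2]}")
    else:
        raise MeshParseError(f"unsupported mesh format: {fmt!r}")
    path.write_text("\n".join(out) + "\n")
    return path
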