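"""3D alpha shapes over viable Euler pose clouds.

Viable poses are treated as points in flat R^3 (FE on axis 1, ABAD on axis 2,
LAR on axis 3, all in degrees, no cosine correction and no angular
wraparound).  The alpha complex keeps the tetrahedra of the Delaunay
tetrahedralization whose circumradius is at most the alpha radius; its
boundary is the set of faces belonging to exactly one retained tetrahedron.
Containment queries are closed (the boundary counts as inside).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

from . import _collision
from .errors import DegenerateGeometryError, MeshError
from .geometry import TriMesh, load_mesh, save_mesh, validate_mesh
from .kinematics import EulerPose

__all__ = [
    "AlphaShape",
    "build_alpha_shape",
    "auto_radius",
    "contains",
    "export_alpha_obj",
    "import_alpha_obj",
]


def _jittered(points: np.ndarray) -> np.ndarray:
    """Deterministic symbolic perturbation before triangulating.

    Regular degree grids are maximally degenerate for Delaunay (cospherical
    and coplanar 4-tuples everywhere); the resulting zero-volume tetrahedra
    have no well-defined circumsphere and excluding them cracks the alpha
    boundary open at every radius.  A fixed sub-microdegree jitter (1e-9 of
    the bounding-box diagonal, seeded constant) resolves the degeneracy
    while moving every point by far less than any meaningful tolerance.
    """
    diag = float(np.linalg.norm(points.max(0) - points.min(0)))
    if diag == 0.0:
        diag = 1.0
    rng = np.random.default_rng(0x0A1F4)
    return points + rng.standard_normal(points.shape) * (1e-9 * diag)


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (inf for degenerate ones)."""
    tets = points[simplices]  # (t, 4, 3)
    a = tets[:, 0]
    rhs = np.einsum("tij,tij->ti", tets[:, 1:], tets[:, 1:]) - np.einsum(
        "tj,tj->t", a, a
    )[:, None]
    mat = 2.0 * (tets[:, 1:] - a[:, None, :])
    radii = np.full(len(tets), np.inf)
    det = np.linalg.det(mat)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers = np.linalg.solve(mat[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - a[ok], axis=1)
    return radii


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    tets = points[simplices]
    e = tets[:, 1:] - tets[:, :1]
    return np.abs(np.linalg.det(e)) / 6.0


# faces of a tetrahedron (vertex index triples) with the opposite vertex
_TET_FACES = ((1, 2, 3, 0), (0, 2, 3, 1), (0, 1, 3, 2), (0, 1, 2, 3))


def _boundary_mesh(points: np.ndarray, simplices: np.ndarray) -> TriMesh:
    """Outward-oriented boundary of a union of tetrahedra."""
    if len(simplices) == 0:
        return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64),
                       "alpha_boundary")
    simplices = np.asarray(simplices, dtype=np.int64)
    # all 4 faces of every tet, with the opposite vertex alongside
    tris = np.concatenate(
        [simplices[:, [i, j, k]] for i, j, k, _ in _TET_FACES]
    )
    opps = np.concatenate([simplices[:, o] for _, _, _, o in _TET_FACES])
    key = np.sort(tris, axis=1)
    _, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    on_boundary = counts[inverse] == 1  # interior faces belong to two tets
    tris = tris[on_boundary]
    opps = opps[on_boundary]
    a, b, c = points[tris[:, 0]], points[tris[:, 1]], points[tris[:, 2]]
    normals = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", normals, points[opps] - a) > 0
    tris[inward] = tris[inward][:, [0, 2, 1]]  # flip to point away from tet
    faces = tris
    used = np.unique(faces)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(points[used], remap[faces], name="alpha_boundary")


@dataclass
class AlphaShape:
    """Alpha complex over generating points plus its boundary surface.

    ``mode`` selects how containment is answered: ``"complex"`` queries the
    retained tetrahedra directly (the native representation); ``"boundary"``
    uses ray-parity against the boundary mesh (used after OBJ import, where
    only the surface survives the round trip).
    """

    generating_points: np.ndarray
    alpha_radius: float
    retained_tetrahedra: np.ndarray
    boundary_mesh: TriMesh
    mode: str = "complex"
    _delaunay: Delaunay | None = field(default=None, repr=False)
    _retained_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_retained(self) -> int:
        return len(self.retained_tetrahedra)

    def volume(self) -> float:
        """Total volume of retained tetrahedra (cubic degrees; comparative
        only, since Euler space is not cosine-corrected)."""
        if self.mode == "complex":
            return float(
                _tet_volumes(
                    self.generating_points, self.retained_tetrahedra
                ).sum()
            )
        v = self.boundary_mesh.vertices
        f = self.boundary_mesh.faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        return abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))

    def contains_points(self, query: np.ndarray, tol: float = 1e-6):
        query = np.atleast_2d(np.asarray(query, dtype=float))
        if self.mode == "boundary":
            return self._contains_by_parity(query, tol)
        out = np.zeros(len(query), dtype=bool)
        if self._delaunay is not None and self._retained_mask is not None:
            simp = self._delaunay.find_simplex(query, tol=tol)
            hit = simp >= 0
            out[hit] = self._retained_mask[simp[hit]]
            todo = np.nonzero(~out)[0]
        else:
            todo = np.arange(len(query))
        if len(todo):
            out[todo] = self._contains_barycentric(query[todo], tol)
        return out

    def _contains_barycentric(self, query: np.ndarray, tol: float):
        """Closed membership against every retained tetrahedron."""
        pts = (
            self._delaunay.points
            if self._delaunay is not None
            else self.generating_points
        )
        tets = self.retained_tetrahedra
        lo = pts[tets].min(axis=1) - tol
        hi = pts[tets].max(axis=1) + tol
        out = np.zeros(len(query), dtype=bool)
        for qi, q in enumerate(query):
            cand = np.nonzero(
                np.all((q >= lo) & (q <= hi), axis=1)
            )[0]
            for ti in cand:
                a, b, c, d = pts[tets[ti]]
                m = np.column_stack([b - a, c - a, d - a])
                det = np.linalg.det(m)
                if abs(det) < 1e-14:
                    continue
                bary = np.linalg.solve(m, q - a)
                if bary.min() >= -1e-6 and bary.sum() <= 1.0 + 1e-6:
                    out[qi] = True
                    break
        return out

    def _contains_by_parity(self, query: np.ndarray, tol: float):
        v = self.boundary_mesh.vertices
        f = self.boundary_mesh.faces
        out = np.zeros(len(query), dtype=bool)
        for qi, q in enumerate(query):
            try:
                inside = _collision.point_in_mesh(q, v, f)
            except RuntimeError:
                inside = True  # ray degenerate: on-surface point, closed => in
            if not inside:
                # closed containment: points on the surface count as inside
                d = min(
                    _collision.point_triangle_distance(
                        q, v[tri[0]], v[tri[1]], v[tri[2]]
                    )
                    for tri in f
                )
                inside = d <= tol
            out[qi] = inside
        return out


def build_alpha_shape(points, alpha_radius: float) -> AlphaShape:
    """Alpha complex of a viable-pose point cloud at a given radius (deg)."""
    points = np.ascontiguousarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (n, 3): (fe, abad, lar) degrees")
    if len(points) < 4:
        raise DegenerateGeometryError("need at least 4 points")
    if not alpha_radius > 0:
        raise ValueError("alpha radius must be positive")
    span = points.max(0) - points.min(0)
    if np.sort(span)[0] <= 1e-9 or len(np.unique(points, axis=0)) < 4:
        raise DegenerateGeometryError(
            "degenerate point set (coplanar/collinear)"
        )
    try:
        tri = Delaunay(_jittered(points))
    except QhullError as exc:
        raise DegenerateGeometryError(
            "degenerate point set (coplanar/collinear)"
        ) from exc
    if tri.simplices.shape[1] != 4:
        raise DegenerateGeometryError("point set is not full-dimensional")
    radii = _circumradii(tri.points, tri.simplices)
    return _assemble(points, tri, radii, float(alpha_radius))


def _assemble(
    points: np.ndarray, tri: Delaunay, radii: np.ndarray, alpha: float
) -> AlphaShape:
    mask = radii <= alpha + 1e-9
    retained = tri.simplices[mask]
    boundary = _boundary_mesh(tri.points, retained)
    return AlphaShape(
        generating_points=points,
        alpha_radius=alpha,
        retained_tetrahedra=retained,
        boundary_mesh=boundary,
        mode="complex",
        _delaunay=tri,
        _retained_mask=mask,
    )


def _vertex_cover_radius(
    n_points: int, simplices: np.ndarray, radii: np.ndarray
) -> float:
    """Smallest alpha at which every generating point joins the complex.

    A point is contained iff it is a vertex of some retained tetrahedron, so
    the wrapping radius is max over points of the min circumradius among the
    tetrahedra incident to it.
    """
    best = np.full(n_points, np.inf)
    for ti, tet in enumerate(simplices):
        r = radii[ti]
        for v in tet:
            if r < best[v]:
                best[v] = r
    return float(best.max())


def auto_radius(
    points, resolution_deg: float = 0.5, max_radius: float | None = None
) -> float:
    """Smallest lattice radius wrapping all points with a clean boundary.

    Mirrors the manual protocol of growing the alpha radius until the shape
    wraps every viable pose: bisect the resolution lattice for the smallest
    radius containing all generating points, then step upward until the
    boundary mesh also passes the cleanliness audit (manifold, consistently
    wound, no self-intersections).  Raises if no clean radius exists up to
    the convex-hull-equivalent limit.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    if len(points) < 4:
        raise DegenerateGeometryError("need at least 4 points")
    try:
        tri = Delaunay(_jittered(points))
    except QhullError as exc:
        raise DegenerateGeometryError(
            "degenerate point set (coplanar/collinear)"
        ) from exc
    res = float(resolution_deg)
    if res <= 0:
        raise ValueError("resolution must be positive")
    radii = _circumradii(tri.points, tri.simplices)
    finite = radii[np.isfinite(radii)]
    hull_equiv = float(finite.max()) if len(finite) else res
    if max_radius is None:
        max_radius = hull_equiv + res
    need = _vertex_cover_radius(len(points), tri.simplices, radii)
    # bisection over lattice indices for the containment (monotone) condition
    lo_i, hi_i = 0, int(np.ceil(max_radius / res)) + 1
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if mid * res >= need - 1e-12:
            hi_i = mid
        else:
            lo_i = mid + 1
    start = max(lo_i, 1) * res
    # scan upward for cleanliness (not monotone), but only at lattice radii
    # where the retained complex actually changes
    finite_sorted = np.sort(finite)
    change_radii = np.unique(np.ceil(finite_sorted / res) * res)
    candidates = [start] + [r for r in change_radii if r > start + 1e-12]
    for r in candidates:
        if r > max_radius + res:
            break
        shape = _assemble(points, tri, radii, float(r))
        if validate_mesh(shape.boundary_mesh).clean:
            return float(r)
    raise MeshError(
        "no alpha radius up to the convex-hull limit yields a clean boundary"
    )


def contains(shape: AlphaShape, pose) -> bool:
    """Closed containment of an Euler pose in the alpha complex."""
    if isinstance(pose, EulerPose):
        point = pose.as_array()
    else:
        point = np.asarray(pose, dtype=float).reshape(3)
    return bool(shape.contains_points(point[None, :])[0])


def export_alpha_obj(shape: AlphaShape, path) -> Path:
    """Write the boundary mesh as OBJ (vertices in degree units).

    Unclean boundaries are refused: downstream containment via the surface
    requires a manifold, consistently wound, self-intersection-free mesh.
    """
    report = validate_mesh(shape.boundary_mesh)
    if not report.clean:
        raise MeshError(
            "alpha boundary mesh is not clean "
            f"(watertight={report.watertight}, manifold={report.manifold}, "
            f"consistent_normals={report.consistent_normals}, "
            f"self_intersecting={report.self_intersecting}); export refused"
        )
    return save_mesh(shape.boundary_mesh, path, "obj")


def import_alpha_obj(path, generating_points=None, alpha_radius=0.0):
    """Rebuild an AlphaShape from an exported boundary OBJ.

    Containment is answered by ray parity against the surface, which agrees
    with the original complex for every query not exactly on the boundary.
    """
    mesh = load_mesh(path, "obj")
    report = validate_mesh(mesh)
    if not report.clean:
        raise MeshError(f"imported alpha mesh {path} is not clean")
    pts = (
        np.zeros((0, 3))
        if generating_points is None
        else np.asarray(generating_points, dtype=float)
    )
    return AlphaShape(
        generating_points=pts,
        alpha_radius=float(alpha_radius),
        retained_tetrahedra=np.zeros((0, 4), dtype=np.int64),
        boundary_mesh=mesh,
        mode="boundary",
    )


def convex_hull_volume(points) -> float:
    """Convex-hull volume of a point cloud (independent reference for the
    large-radius limit of alpha shapes)."""
    return float(ConvexHull(np.asarray(points, dtype=float)).volume)
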