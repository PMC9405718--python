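"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's numba collision kernels and alpha
complex queries: collisions are decided by explicit edge-plane clipping over
all triangle pairs plus a numpy ray-parity containment test, and alpha-shape
membership by dense barycentric solves over every retained tetrahedron.
"""
from __future__ import annotations

import numpy as np

EPS = 1e-9


def _plane(tri):
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    return n, tri[0]


def _segment_on_line(tri, dists, line_p, line_d):
    """Intersection segment (as scalar interval on the line) of a triangle
    crossing a plane, from explicit edge-plane intersection points."""
    pts = []
    for i in range(3):
        j = (i + 1) % 3
        di, dj = dists[i], dists[j]
        if (di > 0 > dj) or (di < 0 < dj):
            t = di / (di - dj)
            pts.append(tri[i] + t * (tri[j] - tri[i]))
        elif abs(di) <= 0:
            pts.append(tri[i])
    params = [float((p - line_p) @ line_d) for p in pts]
    return min(params), max(params)


def tri_tri_cross(t1, t2):
    """Proper crossing of two triangles (tangency excluded)."""
    n2, q0 = _plane(t2)
    d1 = np.array([(v - q0) @ n2 for v in t1])
    tol2 = EPS * max(np.linalg.norm(n2), EPS)
    if (d1 > tol2).all() or (d1 < -tol2).all():
        return False
    n1, p0 = _plane(t1)
    d2 = np.array([(v - p0) @ n1 for v in t2])
    tol1 = EPS * max(np.linalg.norm(n1), EPS)
    if (d2 > tol1).all() or (d2 < -tol1).all():
        return False
    if not ((d1 > tol2).any() and (d1 < -tol2).any()):
        return False
    if not ((d2 > tol1).any() and (d2 < -tol1).any()):
        return False
    line_d = np.cross(n1, n2)
    norm = np.linalg.norm(line_d)
    if norm < 1e-14:
        return False  # coplanar: tangent contact only
    line_d = line_d / norm
    lo1, hi1 = _segment_on_line(t1, d1, p0, line_d)
    lo2, hi2 = _segment_on_line(t2, d2, p0, line_d)
    return min(hi1, hi2) - max(lo1, lo2) > EPS


def point_in_mesh_numpy(point, verts, faces, rng=None):
    """Ray-parity containment with a random (seeded) ray direction,
    retrying on grazing hits."""
    if rng is None:
        rng = np.random.default_rng(12345)
    tris = verts[faces]
    for _ in range(16):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        v0 = tris[:, 0]
        e1 = tris[:, 1] - v0
        e2 = tris[:, 2] - v0
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        t0 = point - v0
        u = np.einsum("ij,ij->i", t0, p) * inv
        q = np.cross(t0, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u > 0) & (v > 0) & (u + v < 1) & (t > 0)
        grazing = ok & (t > -1e-9) & (
            (np.abs(u) < 1e-9)
            | (np.abs(v) < 1e-9)
            | (np.abs(1 - u - v) < 1e-9)
            | (np.abs(t) < 1e-9)
        ) & (u > -1e-9) & (v > -1e-9) & (u + v < 1 + 1e-9)
        if grazing.any():
            continue
        return bool(hit.sum() & 1)
    raise RuntimeError("all oracle rays grazed the mesh")


def brute_meshes_intersect(va, fa, vb, fb):
    """All-pairs triangle crossing + mutual ray-parity containment."""
    ta = va[fa]
    tb = vb[fb]
    # vectorized plane-side prefilter to keep the python loop tractable
    n2 = np.cross(tb[:, 1] - tb[:, 0], tb[:, 2] - tb[:, 0])  # (m, 3)
    d = np.einsum("mk,nik->nmi", n2, ta) - np.einsum(
        "mk,mk->m", n2, tb[:, 0]
    )[None, :, None]
    tol = EPS * np.maximum(np.linalg.norm(n2, axis=1), EPS)[None, :, None]
    straddle = ~((d > tol).all(axis=2) | (d < -tol).all(axis=2))
    for i, j in zip(*np.nonzero(straddle)):
        if tri_tri_cross(ta[i], tb[j]):
            return True
    if point_in_mesh_numpy(va[0], vb, fb):
        return True
    if point_in_mesh_numpy(vb[0], va, fa):
        return True
    return False


def inconsistent_faces(faces):
    """Half-edge orientation audit: indices of faces that traverse a shared
    edge in the same direction as a neighbor."""
    directed: dict[tuple, list] = {}
    for fi, f in enumerate(faces):
        a, b, c = int(f[0]), int(f[1]), int(f[2])
        for e in ((a, b), (b, c), (c, a)):
            directed.setdefault(e, []).append(fi)
    bad = set()
    for e, owners in directed.items():
        if len(owners) > 1:
            bad.update(owners)
    return sorted(bad)


def barycentric_membership(points, tets, queries, tol=1e-6):
    """Dense closed membership of queries in a union of tetrahedra."""
    queries = np.atleast_2d(queries)
    out = np.zeros(len(queries), dtype=bool)
    for tet in tets:
        a, b, c, d = points[tet]
        m = np.column_stack([b - a, c - a, d - a])
        if abs(np.linalg.det(m)) < 1e-14:
            continue
        bary = np.linalg.solve(m, (queries - a).T).T
        inside = (bary.min(axis=1) >= -tol) & (bary.sum(axis=1) <= 1 + tol)
        out |= inside
        if out.all():
            break
    return out


def elementary_euler_product(fe_deg, abad_deg, lar_deg):
    """Explicit term-by-term product of the three elementary rotations."""
    def rot(axis, deg):
        a = np.deg2rad(deg)
        c, s = np.cos(a), np.sin(a)
        if axis == "z":
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        if axis == "y":
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    return rot("z", fe_deg) @ rot("y", abad_deg) @ rot("x", lar_deg)
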