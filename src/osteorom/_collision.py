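"""Low-level collision kernels (numba-compiled).

All predicates implement *strict* interpenetration semantics: triangle pairs
that merely touch (share a point, edge, or lie in a common plane) within
``EPS`` do not count as intersecting.  This matches the convention that exact
surface tangency between articulating bones leaves a pose viable.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# Absolute tolerance in mesh units (mm).  Coordinates in this package are
# O(1)-O(100) mm, so 1e-9 separates genuine crossings from contact noise.
EPS = 1e-9

# Ray directions for parity tests, deliberately irrational-ish so that rays
# through mesh vertices/edges are vanishingly unlikely; retried in order when
# a grazing hit is detected.
_RAY_DIRS = np.array(
    [
        [0.57735026, 0.57735027, 0.57735028],
        [0.26726124, 0.53452248, 0.80178373],
        [-0.80178373, 0.26726124, 0.53452248],
        [0.12309149, -0.49236596, 0.86164044],
        [0.90453403, -0.30151134, 0.30151134],
        [-0.31622777, -0.63245553, 0.70710678],
        [0.42426407, 0.56568542, -0.70710678],
        [-0.16903085, 0.84515425, -0.50709255],
    ]
)


@njit(cache=True, inline="always")
def _cross(ax, ay, az, bx, by, bz):
    return ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx


@njit(cache=True)
def _interval(proj0, proj1, proj2, d0, d1, d2):
    """Interval of the intersection line covered by a triangle.

    ``proj`` are vertex projections on the line, ``d`` signed distances to the
    other triangle's plane (mixed signs guaranteed by the caller).  Returns
    (lo, hi).
    """
    # signs with zeros folded into the positive side
    s0 = 1 if d0 > 0.0 else -1
    s1 = 1 if d1 > 0.0 else -1
    s2 = 1 if d2 > 0.0 else -1
    if s0 == s1:
        a, b, c = 2, 0, 1
    elif s0 == s2:
        a, b, c = 1, 0, 2
    else:
        a, b, c = 0, 1, 2
    pa, pb, pc = proj0, proj1, proj2
    da, db, dc = d0, d1, d2
    if a == 1:
        pa, pb, pc = proj1, proj0, proj2
        da, db, dc = d1, d0, d2
    elif a == 2:
        pa, pb, pc = proj2, proj0, proj1
        da, db, dc = d2, d0, d1
    t1 = pa + (pb - pa) * da / (da - db)
    t2 = pa + (pc - pa) * da / (da - dc)
    if t1 > t2:
        t1, t2 = t2, t1
    return t1, t2


@njit(cache=True)
def tri_tri_intersect(
    p0x, p0y, p0z, p1x, p1y, p1z, p2x, p2y, p2z,
    q0x, q0y, q0z, q1x, q1y, q1z, q2x, q2y, q2z,
):
    """Moller-style interval test; True only for proper (strict) crossings."""
    # plane of Q
    e1x, e1y, e1z = q1x - q0x, q1y - q0y, q1z - q0z
    e2x, e2y, e2z = q2x - q0x, q2y - q0y, q2z - q0z
    n2x, n2y, n2z = _cross(e1x, e1y, e1z, e2x, e2y, e2z)
    dp0 = n2x * (p0x - q0x) + n2y * (p0y - q0y) + n2z * (p0z - q0z)
    dp1 = n2x * (p1x - q0x) + n2y * (p1y - q0y) + n2z * (p1z - q0z)
    dp2 = n2x * (p2x - q0x) + n2y * (p2y - q0y) + n2z * (p2z - q0z)
    n2len = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    tol2 = EPS * max(n2len, EPS)
    if (dp0 > tol2 and dp1 > tol2 and dp2 > tol2) or (
        dp0 < -tol2 and dp1 < -tol2 and dp2 < -tol2
    ):
        return False
    # plane of P
    f1x, f1y, f1z = p1x - p0x, p1y - p0y, p1z - p0z
    f2x, f2y, f2z = p2x - p0x, p2y - p0y, p2z - p0z
    n1x, n1y, n1z = _cross(f1x, f1y, f1z, f2x, f2y, f2z)
    dq0 = n1x * (q0x - p0x) + n1y * (q0y - p0y) + n1z * (q0z - p0z)
    dq1 = n1x * (q1x - p0x) + n1y * (q1y - p0y) + n1z * (q1z - p0z)
    dq2 = n1x * (q2x - p0x) + n1y * (q2y - p0y) + n1z * (q2z - p0z)
    n1len = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    tol1 = EPS * max(n1len, EPS)
    if (dq0 > tol1 and dq1 > tol1 and dq2 > tol1) or (
        dq0 < -tol1 and dq1 < -tol1 and dq2 < -tol1
    ):
        return False
    # A proper crossing needs each triangle to straddle the other's plane
    # strictly; anything else (coplanar, vertex/edge contact) is tangency.
    if not (
        (dp0 > tol2 or dp1 > tol2 or dp2 > tol2)
        and (dp0 < -tol2 or dp1 < -tol2 or dp2 < -tol2)
    ):
        return False
    if not (
        (dq0 > tol1 or dq1 > tol1 or dq2 > tol1)
        and (dq0 < -tol1 or dq1 < -tol1 or dq2 < -tol1)
    ):
        return False
    # direction of intersection line; project on dominant axis
    dx, dy, dz = _cross(n1x, n1y, n1z, n2x, n2y, n2z)
    ax_, ay_, az_ = abs(dx), abs(dy), abs(dz)
    if ax_ >= ay_ and ax_ >= az_:
        pp0, pp1, pp2 = p0x, p1x, p2x
        qq0, qq1, qq2 = q0x, q1x, q2x
    elif ay_ >= az_:
        pp0, pp1, pp2 = p0y, p1y, p2y
        qq0, qq1, qq2 = q0y, q1y, q2y
    else:
        pp0, pp1, pp2 = p0z, p1z, p2z
        qq0, qq1, qq2 = q0z, q1z, q2z
    lo1, hi1 = _interval(pp0, pp1, pp2, dp0, dp1, dp2)
    lo2, hi2 = _interval(qq0, qq1, qq2, dq0, dq1, dq2)
    lo = lo1 if lo1 > lo2 else lo2
    hi = hi1 if hi1 < hi2 else hi2
    return hi - lo > EPS


@njit(cache=True)
def _tri_aabbs(verts, faces, out):
    for i in range(faces.shape[0]):
        a, b, c = faces[i, 0], faces[i, 1], faces[i, 2]
        for k in range(3):
            va, vb, vc = verts[a, k], verts[b, k], verts[c, k]
            lo = min(va, min(vb, vc))
            hi = max(va, max(vb, vc))
            out[i, k] = lo - EPS
            out[i, 3 + k] = hi + EPS


@njit(cache=True)
def any_pair_intersects(va, fa, vb, fb):
    """True if any triangle of mesh A properly crosses any triangle of B."""
    boxa = np.empty((fa.shape[0], 6))
    boxb = np.empty((fb.shape[0], 6))
    _tri_aabbs(va, fa, boxa)
    _tri_aabbs(vb, fb, boxb)
    for i in range(fa.shape[0]):
        ai0, ai1, ai2 = fa[i, 0], fa[i, 1], fa[i, 2]
        for j in range(fb.shape[0]):
            if (
                boxa[i, 0] > boxb[j, 3] or boxa[i, 3] < boxb[j, 0]
                or boxa[i, 1] > boxb[j, 4] or boxa[i, 4] < boxb[j, 1]
                or boxa[i, 2] > boxb[j, 5] or boxa[i, 5] < boxb[j, 2]
            ):
                continue
            bj0, bj1, bj2 = fb[j, 0], fb[j, 1], fb[j, 2]
            if tri_tri_intersect(
                va[ai0, 0], va[ai0, 1], va[ai0, 2],
                va[ai1, 0], va[ai1, 1], va[ai1, 2],
                va[ai2, 0], va[ai2, 1], va[ai2, 2],
                vb[bj0, 0], vb[bj0, 1], vb[bj0, 2],
                vb[bj1, 0], vb[bj1, 1], vb[bj1, 2],
                vb[bj2, 0], vb[bj2, 1], vb[bj2, 2],
            ):
                return True
    return False


@njit(cache=True)
def _ray_parity(ox, oy, oz, dx, dy, dz, verts, faces):
    """Parity of ray-mesh crossings; -1 if a grazing hit makes it ambiguous."""
    count = 0
    for i in range(faces.shape[0]):
        a, b, c = faces[i, 0], faces[i, 1], faces[i, 2]
        v0x, v0y, v0z = verts[a, 0], verts[a, 1], verts[a, 2]
        e1x, e1y, e1z = verts[b, 0] - v0x, verts[b, 1] - v0y, verts[b, 2] - v0z
        e2x, e2y, e2z = verts[c, 0] - v0x, verts[c, 1] - v0y, verts[c, 2] - v0z
        px, py, pz = _cross(dx, dy, dz, e2x, e2y, e2z)
        det = e1x * px + e1y * py + e1z * pz
        scale = (
            abs(e1x) + abs(e1y) + abs(e1z) + abs(e2x) + abs(e2y) + abs(e2z)
        )
        if abs(det) < 1e-12 * scale * scale:
            # ray parallel to triangle plane: only ambiguous if it grazes it
            continue
        inv = 1.0 / det
        tx, ty, tz = ox - v0x, oy - v0y, oz - v0z
        u = (tx * px + ty * py + tz * pz) * inv
        if u < -1e-9 or u > 1.0 + 1e-9:
            continue
        qx, qy, qz = _cross(tx, ty, tz, e1x, e1y, e1z)
        v = (dx * qx + dy * qy + dz * qz) * inv
        if v < -1e-9 or u + v > 1.0 + 1e-9:
            continue
        t = (e2x * qx + e2y * qy + e2z * qz) * inv
        if t < -1e-9:
            continue
        if (
            t < 1e-9
            or u < 1e-9 or v < 1e-9 or u + v > 1.0 - 1e-9
        ):
            return -1  # grazing: origin on surface or ray through edge/vertex
        count += 1
    return count & 1


@njit(cache=True)
def point_in_mesh_kernel(px, py, pz, verts, faces, dirs):
    for k in range(dirs.shape[0]):
        r = _ray_parity(px, py, pz, dirs[k, 0], dirs[k, 1], dirs[k, 2],
                        verts, faces)
        if r >= 0:
            return r
    return -1


def point_in_mesh(point, verts, faces):
    """Ray-parity point-in-solid test for a watertight mesh.

    A point exactly on the surface may report either side; callers that need
    closed semantics must handle the boundary separately.
    """
    r = point_in_mesh_kernel(
        float(point[0]), float(point[1]), float(point[2]),
        np.ascontiguousarray(verts, dtype=np.float64),
        np.ascontiguousarray(faces, dtype=np.int64),
        _RAY_DIRS,
    )
    if r < 0:
        raise RuntimeError("ray-parity test degenerate for all ray directions")
    return bool(r)


@njit(cache=True)
def self_intersects(verts, faces):
    """Any proper crossing between triangles not sharing a vertex."""
    box = np.empty((faces.shape[0], 6))
    _tri_aabbs(verts, faces, box)
    n = faces.shape[0]
    for i in range(n):
        a0, a1, a2 = faces[i, 0], faces[i, 1], faces[i, 2]
        for j in range(i + 1, n):
            if (
                box[i, 0] > box[j, 3] or box[i, 3] < box[j, 0]
                or box[i, 1] > box[j, 4] or box[i, 4] < box[j, 1]
                or box[i, 2] > box[j, 5] or box[i, 5] < box[j, 2]
            ):
                continue
            b0, b1, b2 = faces[j, 0], faces[j, 1], faces[j, 2]
            if (
                a0 == b0 or a0 == b1 or a0 == b2
                or a1 == b0 or a1 == b1 or a1 == b2
                or a2 == b0 or a2 == b1 or a2 == b2
            ):
                continue
            if tri_tri_intersect(
                verts[a0, 0], verts[a0, 1], verts[a0, 2],
                verts[a1, 0], verts[a1, 1], verts[a1, 2],
                verts[a2, 0], verts[a2, 1], verts[a2, 2],
                verts[b0, 0], verts[b0, 1], verts[b0, 2],
                verts[b1, 0], verts[b1, 1], verts[b1, 2],
                verts[b2, 0], verts[b2, 1], verts[b2, 2],
            ):
                return True
    return False


@njit(cache=True)
def sweep_poses(
    prox_verts, prox_faces, prox_boxes,
    u_verts, dist_faces, center,
    rot_mats, pair_d, pair_p, viable,
):
    """Per-pose collision sweep of a single rotating joint.

    ``u_verts`` are distal-mesh vertices expressed relative to the fixed
    rotation ``center`` (proximal-ACS-local frame); pose k places vertex i at
    ``center + rot_mats[k] @ u_verts[i]``.  ``pair_d``/``pair_p`` enumerate the
    candidate (distal, proximal) triangle pairs that survive the static
    radial-interval prefilter.  Writes True into ``viable[k]`` when pose k has
    no strict interpenetration (crossing or containment).
    """
    nd = u_verts.shape[0]
    ndt = dist_faces.shape[0]
    w = np.empty((nd, 3))
    dbox = np.empty((ndt, 6))
    npairs = pair_d.shape[0]
    for k in range(rot_mats.shape[0]):
        r00, r01, r02 = rot_mats[k, 0, 0], rot_mats[k, 0, 1], rot_mats[k, 0, 2]
        r10, r11, r12 = rot_mats[k, 1, 0], rot_mats[k, 1, 1], rot_mats[k, 1, 2]
        r20, r21, r22 = rot_mats[k, 2, 0], rot_mats[k, 2, 1], rot_mats[k, 2, 2]
        for i in range(nd):
            ux, uy, uz = u_verts[i, 0], u_verts[i, 1], u_verts[i, 2]
            w[i, 0] = center[0] + r00 * ux + r01 * uy + r02 * uz
            w[i, 1] = center[1] + r10 * ux + r11 * uy + r12 * uz
            w[i, 2] = center[2] + r20 * ux + r21 * uy + r22 * uz
        _tri_aabbs(w, dist_faces, dbox)
        hit = False
        for p in range(npairs):
            i = pair_d[p]
            j = pair_p[p]
            if (
                dbox[i, 0] > prox_boxes[j, 3] or dbox[i, 3] < prox_boxes[j, 0]
                or dbox[i, 1] > prox_boxes[j, 4] or dbox[i, 4] < prox_boxes[j, 1]
                or dbox[i, 2] > prox_boxes[j, 5] or dbox[i, 5] < prox_boxes[j, 2]
            ):
                continue
            a0, a1, a2 = dist_faces[i, 0], dist_faces[i, 1], dist_faces[i, 2]
            b0, b1, b2 = prox_faces[j, 0], prox_faces[j, 1], prox_faces[j, 2]
            if tri_tri_intersect(
                w[a0, 0], w[a0, 1], w[a0, 2],
                w[a1, 0], w[a1, 1], w[a1, 2],
                w[a2, 0], w[a2, 1], w[a2, 2],
                prox_verts[b0, 0], prox_verts[b0, 1], prox_verts[b0, 2],
                prox_verts[b1, 0], prox_verts[b1, 1], prox_verts[b1, 2],
                prox_verts[b2, 0], prox_verts[b2, 1], prox_verts[b2, 2],
            ):
                hit = True
                break
        if not hit:
            # no surface crossing: check mutual containment by parity
            r = point_in_mesh_kernel(
                w[0, 0], w[0, 1], w[0, 2], prox_verts, prox_faces, _RAY_DIRS
            )
            if r == 1:
                hit = True
            elif r == -1:
                hit = True  # conservatively treat unresolvable as contact
            if not hit:
                r = point_in_mesh_kernel(
                    prox_verts[0, 0], prox_verts[0, 1], prox_verts[0, 2],
                    w, dist_faces, _RAY_DIRS,
                )
                if r == 1:
                    hit = True
        viable[k] = not hit


def point_triangle_distance(p, a, b, c):
    """Exact min distance from point ``p`` to triangle ``abc`` (numpy)."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    ac = np.asarray(c, dtype=float) - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(ap))
    bp = p - np.asarray(b, dtype=float)
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(bp))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return float(np.linalg.norm(ap - t * ab))
    cp = p - np.asarray(c, dtype=float)
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(cp))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return float(np.linalg.norm(ap - t * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        bc = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
        return float(np.linalg.norm(bp - t * bc))
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    closest = a + ab * v + ac * w
    return float(np.linalg.norm(p - closest))
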