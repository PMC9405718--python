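"""Watertight parametric triangle meshes (boxes, lathes, prisms).

Every constructor returns a consistently wound, outward-oriented, watertight
``TriMesh``; the synthetic joint fixtures and the test suite are built on
these.  Construction is purely deterministic.
"""
from __future__ import annotations

import numpy as np

from .geometry import TriMesh

__all__ = [
    "make_box",
    "make_uv_sphere",
    "make_cylinder",
    "make_spherical_shell_cap",
    "revolve_profile",
    "make_annular_sector_prism",
    "concatenate_meshes",
    "signed_volume",
]


def signed_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume (positive for outward-wound closed meshes)."""
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def _oriented(vertices: np.ndarray, faces: np.ndarray, name: str) -> TriMesh:
    mesh = TriMesh(vertices, faces, name=name)
    if signed_volume(mesh) < 0:
        mesh = TriMesh(vertices, faces[:, ::-1].copy(), name=name)
    return mesh


def make_box(half_sizes, center=(0.0, 0.0, 0.0), name: str = "box") -> TriMesh:
    hx, hy, hz = (float(h) for h in half_sizes)
    cx, cy, cz = (float(c) for c in center)
    corners = np.array(
        [
            [-hx, -hy, -hz], [hx, -hy, -hz], [hx, hy, -hz], [-hx, hy, -hz],
            [-hx, -hy, hz], [hx, -hy, hz], [hx, hy, hz], [-hx, hy, hz],
        ]
    ) + np.array([cx, cy, cz])
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # -z
            [4, 5, 6], [4, 6, 7],  # +z
            [0, 1, 5], [0, 5, 4],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [1, 2, 6], [1, 6, 5],  # +x
            [0, 4, 7], [0, 7, 3],  # -x
        ],
        dtype=np.int64,
    )
    return _oriented(corners, faces, name)


def revolve_profile(profile, n_azimuth: int, name: str = "lathe") -> TriMesh:
    """Revolve a closed (x, rho) profile polygon about the X axis.

    Profile vertices with ``rho == 0`` become single apex vertices; profile
    edges with both endpoints on the axis generate no faces (the solid touches
    the axis only at isolated apex points).  The profile must not
    self-intersect and ``rho`` must be non-negative.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2 or profile.shape[1] != 2 or len(profile) < 3:
        raise ValueError("profile must be an (m, 2) polygon")
    if np.any(profile[:, 1] < -1e-12):
        raise ValueError("profile rho values must be non-negative")
    m = len(profile)
    n = int(n_azimuth)
    if n < 3:
        raise ValueError("n_azimuth must be >= 3")
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    verts: list[np.ndarray] = []
    n_verts = 0
    ring_start = np.full(m, -1, dtype=int)  # first vertex index of each ring
    on_axis = profile[:, 1] <= 1e-12
    for i in range(m):
        ring_start[i] = n_verts
        x, rho = profile[i]
        if on_axis[i]:
            verts.append(np.array([[x, 0.0, 0.0]]))
            n_verts += 1
        else:
            ring = np.column_stack(
                [np.full(n, x), rho * cos_t, rho * sin_t]
            )
            verts.append(ring)
            n_verts += n
    vertices = np.vstack(verts)

    faces: list[tuple[int, int, int]] = []
    for i in range(m):
        j = (i + 1) % m
        ai, aj = on_axis[i], on_axis[j]
        si, sj = ring_start[i], ring_start[j]
        if ai and aj:
            continue
        for k in range(n):
            k1 = (k + 1) % n
            if ai:  # apex at i, ring at j
                faces.append((si, sj + k, sj + k1))
            elif aj:  # ring at i, apex at j
                faces.append((sj, si + k1, si + k))
            else:
                faces.append((si + k, sj + k, sj + k1))
                faces.append((si + k, sj + k1, si + k1))
    return _oriented(vertices, np.asarray(faces, dtype=np.int64), name)


def make_uv_sphere(
    radius: float, center=(0.0, 0.0, 0.0), n_azimuth: int = 24,
    n_polar: int = 12, name: str = "sphere",
) -> TriMesh:
    phi = np.linspace(0.0, np.pi, n_polar + 1)
    profile = np.column_stack([radius * np.cos(phi), radius * np.sin(phi)])
    mesh = revolve_profile(profile, n_azimuth, name=name)
    return TriMesh(mesh.vertices + np.asarray(center, float), mesh.faces, name)


def make_cylinder(
    radius: float, lo: float, hi: float, n_azimuth: int = 24,
    axis: str = "x", name: str = "cylinder",
) -> TriMesh:
    """Closed solid cylinder spanning [lo, hi] along the given axis."""
    if hi <= lo:
        raise ValueError("cylinder extent must be positive")
    profile = np.array(
        [[lo, 0.0], [lo, radius], [hi, radius], [hi, 0.0]]
    )
    mesh = revolve_profile(profile, n_azimuth, name=name)
    v = mesh.vertices
    if axis == "x":
        pass
    elif axis == "y":
        v = v[:, [2, 0, 1]].copy()
    elif axis == "z":
        v = v[:, [1, 2, 0]].copy()
    else:
        raise ValueError("axis must be one of x, y, z")
    return _oriented(v, mesh.faces, name)


def make_spherical_shell_cap(
    r_inner: float, r_outer: float, rim_polar_deg: float,
    n_azimuth: int = 32, n_polar: int = 12, name: str = "shell_cap",
) -> TriMesh:
    """Spherical shell segment covering polar angles [rim, 180] about +X.

    The solid is ``{p : r_inner <= |p| <= r_outer, polar(p) >= rim}`` with the
    polar angle measured from the +X axis: a cup opening toward +X whose rim
    circle sits at polar angle ``rim_polar_deg``.
    """
    if not (0.0 < r_inner < r_outer):
        raise ValueError("need 0 < r_inner < r_outer")
    if not (0.0 < rim_polar_deg < 180.0):
        raise ValueError("rim polar angle must be in (0, 180) degrees")
    rim = np.deg2rad(rim_polar_deg)
    phi = np.linspace(rim, np.pi, n_polar + 1)
    inner = np.column_stack([r_inner * np.cos(phi), r_inner * np.sin(phi)])
    outer = np.column_stack(
        [r_outer * np.cos(phi[::-1]), r_outer * np.sin(phi[::-1])]
    )
    profile = np.vstack([inner, outer])  # closes rim->rim implicitly
    return revolve_profile(profile, n_azimuth, name=name)


def make_annular_sector_prism(
    r_inner: float, r_outer: float, z_lo: float, z_hi: float,
    az_lo_deg: float, az_hi_deg: float, n_azimuth: int = 48,
    name: str = "sector",
) -> TriMesh:
    """Solid annular sector around the Z axis (a C-ring when az span < 360)."""
    if not (0.0 < r_inner < r_outer) or z_hi <= z_lo:
        raise ValueError("invalid sector dimensions")
    if az_hi_deg <= az_lo_deg or az_hi_deg - az_lo_deg >= 360.0:
        raise ValueError("azimuth span must be in (0, 360) degrees")
    theta = np.deg2rad(np.linspace(az_lo_deg, az_hi_deg, n_azimuth + 1))
    ct, st = np.cos(theta), np.sin(theta)
    m = n_azimuth + 1
    # 4 vertices per azimuth sample: (ri,zlo), (ro,zlo), (ro,zhi), (ri,zhi)
    verts = np.empty((4 * m, 3))
    for k, (r, z) in enumerate(
        [(r_inner, z_lo), (r_outer, z_lo), (r_outer, z_hi), (r_inner, z_hi)]
    ):
        verts[k * m:(k + 1) * m, 0] = r * ct
        verts[k * m:(k + 1) * m, 1] = r * st
        verts[k * m:(k + 1) * m, 2] = z
    faces: list[tuple[int, int, int]] = []

    def strip(row_a: int, row_b: int) -> None:
        for i in range(n_azimuth):
            a0, a1 = row_a * m + i, row_a * m + i + 1
            b0, b1 = row_b * m + i, row_b * m + i + 1
            faces.append((a0, b0, b1))
            faces.append((a0, b1, a1))

    strip(0, 1)  # bottom
    strip(1, 2)  # outer wall
    strip(2, 3)  # top
    strip(3, 0)  # inner wall
    # end caps at az_lo (i=0) and az_hi (i=n_azimuth)
    for i, flip in ((0, True), (n_azimuth, False)):
        q = [0 * m + i, 1 * m + i, 2 * m + i, 3 * m + i]
        if flip:
            q = q[::-1]
        faces.append((q[0], q[1], q[2]))
        faces.append((q[0], q[2], q[3]))
    return _oriented(verts, np.asarray(faces, dtype=np.int64), name)


def concatenate_meshes(meshes, name: str = "assembly") -> TriMesh:
    """Disjoint union of meshes as one multi-component TriMesh."""
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += len(m.vertices)
    return TriMesh(np.vstack(verts), np.vstack(faces), name=name)
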