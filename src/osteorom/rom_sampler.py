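"""Exhaustive Euler-grid sampling of a joint's pose space.

A joint is swept over a half-open Cartesian grid of (FE, ABAD, LAR) triplets
(default 5 degree steps over [-180, 180) x [-90, 90) x [-180, 180), i.e.
72 * 36 * 72 = 186,624 unique poses) and each pose is marked viable iff the
posed distal bone mesh does not interpenetrate the proximal one.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _collision
from .errors import GridError, MeshError
from .geometry import TriMesh
from .kinematics import EulerPose, JointDefinition, euler_matrices

__all__ = [
    "SampleGrid",
    "ViabilityGrid",
    "RomSummary",
    "generate_grid",
    "sample_rom",
    "summarize_rom",
    "write_viability_csv",
    "read_viability_csv",
]

STANDARD_RANGES = ((-180.0, 180.0), (-90.0, 90.0), (-180.0, 180.0))


def _axis_values(lo: float, hi: float, step: float, label: str) -> np.ndarray:
    width = hi - lo
    if step <= 0:
        raise GridError("step must be positive")
    if width <= 0:
        raise GridError(f"{label} range must have positive width")
    n = width / step
    if abs(n - round(n)) > 1e-9:
        raise GridError(
            f"step {step} does not divide the {label} range width {width}"
        )
    return lo + step * np.arange(int(round(n)))


@dataclass(frozen=True)
class SampleGrid:
    """Half-open Cartesian Euler grid, FE outer / ABAD middle / LAR inner."""

    step_deg: float
    fe_range: tuple
    abad_range: tuple
    lar_range: tuple

    @property
    def fe_values(self) -> np.ndarray:
        return _axis_values(*self.fe_range, self.step_deg, "FE")

    @property
    def abad_values(self) -> np.ndarray:
        return _axis_values(*self.abad_range, self.step_deg, "ABAD")

    @property
    def lar_values(self) -> np.ndarray:
        return _axis_values(*self.lar_range, self.step_deg, "LAR")

    @property
    def n_poses(self) -> int:
        return (
            len(self.fe_values) * len(self.abad_values) * len(self.lar_values)
        )

    def poses(self) -> np.ndarray:
        """(n, 3) array of (fe, abad, lar) triplets in deterministic order."""
        fe, ab, la = np.meshgrid(
            self.fe_values, self.abad_values, self.lar_values, indexing="ij"
        )
        return np.column_stack([fe.ravel(), ab.ravel(), la.ravel()])


def generate_grid(
    step_deg: float = 5.0,
    fe_range=STANDARD_RANGES[0],
    abad_range=STANDARD_RANGES[1],
    lar_range=STANDARD_RANGES[2],
) -> SampleGrid:
    """Build and validate a half-open sampling grid.

    Half-open intervals exclude the +180 / +90 endpoints so that poses
    identical to the -180 / -90 samples are not double counted; the default
    5-degree grid therefore contains exactly 186,624 unique poses.
    """
    grid = SampleGrid(
        float(step_deg), tuple(map(float, fe_range)),
        tuple(map(float, abad_range)), tuple(map(float, lar_range)),
    )
    _ = grid.n_poses  # trigger validation of all three axes
    return grid


@dataclass
class ViabilityGrid:
    """Per-pose viability flags over a sample grid."""

    grid: SampleGrid
    viable: np.ndarray
    joint_name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.viable = np.asarray(self.viable, dtype=bool).ravel()
        if len(self.viable) != self.grid.n_poses:
            raise GridError("one viability flag required per grid pose")

    @property
    def n_viable(self) -> int:
        return int(self.viable.sum())

    def viable_poses(self) -> np.ndarray:
        """(k, 3) Euler triplets of the viable poses."""
        return self.grid.poses()[self.viable]


def _watertight_or_raise(mesh: TriMesh, role: str) -> None:
    from .geometry import _edge_maps

    und, _ = _edge_maps(mesh.faces)
    if len(mesh.faces) == 0 or any(v != 2 for v in und.values()):
        raise MeshError(f"{role} mesh '{mesh.name}' is not watertight")


def _radial_pair_prefilter(
    prox_local: np.ndarray, prox_faces: np.ndarray,
    u_verts: np.ndarray, dist_faces: np.ndarray, center: np.ndarray,
):
    """Candidate (distal, proximal) triangle pairs by radial interval overlap.

    The distal mesh rotates rigidly about ``center``, so each of its vertices
    keeps a fixed distance to the center at every pose; a triangle pair whose
    distance-to-center intervals are disjoint can never touch.  Intervals use
    the exact point-triangle distance as the (conservative) lower bound.
    """
    def tri_intervals(verts, faces, c):
        lo = np.empty(len(faces))
        hi = np.empty(len(faces))
        for i, f in enumerate(faces):
            a, b, d = verts[f[0]], verts[f[1]], verts[f[2]]
            lo[i] = _collision.point_triangle_distance(c, a, b, d)
            hi[i] = max(
                np.linalg.norm(a - c), np.linalg.norm(b - c),
                np.linalg.norm(d - c),
            )
        return lo, hi

    plo, phi = tri_intervals(prox_local, prox_faces, center)
    dlo, dhi = tri_intervals(u_verts, dist_faces, np.zeros(3))
    margin = 1e-6
    overlap = (dlo[:, None] <= phi[None, :] + margin) & (
        plo[None, :] <= dhi[:, None] + margin
    )
    pair_d, pair_p = np.nonzero(overlap)
    return pair_d.astype(np.int64), pair_p.astype(np.int64)


def sample_rom(
    joint: JointDefinition,
    proximal_mesh: TriMesh,
    distal_mesh: TriMesh,
    grid: SampleGrid,
) -> ViabilityGrid:
    """Collision-test every grid pose of a single joint.

    The proximal mesh is fixed in the parent bone frame; the distal mesh is
    posed by the joint's forward kinematics and a pose is viable iff the two
    meshes do not strictly interpenetrate.  Results are deterministic and
    independent of traversal order.
    """
    _watertight_or_raise(proximal_mesh, "proximal")
    _watertight_or_raise(distal_mesh, "distal")

    ap = joint.proximal_acs.matrix
    op = joint.proximal_acs.origin
    ad = joint.distal_acs.matrix
    od = joint.distal_acs.origin
    t = joint.center_fraction
    off = joint.spacing_offset

    # work in the proximal-ACS-local frame where the rotation center is fixed
    prox_local = (proximal_mesh.vertices - op) @ ap
    u_verts = (1.0 - t) * off + (distal_mesh.vertices - od) @ ad
    center = t * off

    pair_d, pair_p = _radial_pair_prefilter(
        prox_local, proximal_mesh.faces, u_verts, distal_mesh.faces, center
    )
    poses = grid.poses()
    rot_mats = euler_matrices(poses)
    viable = np.zeros(len(poses), dtype=np.bool_)
    prox_boxes = np.empty((len(proximal_mesh.faces), 6))
    _collision._tri_aabbs(prox_local, proximal_mesh.faces, prox_boxes)
    _collision.sweep_poses(
        np.ascontiguousarray(prox_local), proximal_mesh.faces, prox_boxes,
        np.ascontiguousarray(u_verts), distal_mesh.faces,
        np.ascontiguousarray(center, dtype=np.float64),
        rot_mats, pair_d, pair_p, viable,
    )
    return ViabilityGrid(
        grid=grid,
        viable=viable,
        joint_name=joint.name,
        provenance={
            "proximal_mesh": proximal_mesh.name,
            "distal_mesh": distal_mesh.name,
            "spacing_offset": [float(x) for x in off],
        },
    )


@dataclass(frozen=True)
class RomSummary:
    """Per-axis extrema over the viable poses, with companion angles.

    ``extrema[(axis, which)]`` is the full (fe, abad, lar) triplet of the
    viable pose achieving the extremum; ``which`` is "max" or "min".
    """

    extrema: dict
    n_viable: int
    n_poses: int

    AXES = ("fe", "abad", "lar")

    def value(self, axis: str, which: str) -> float:
        return self.extrema[(axis, which)][self.AXES.index(axis)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis in self.AXES:
            for which in ("max", "min"):
                fe, ab, la = self.extrema[(axis, which)]
                rows.append(
                    {
                        "axis": axis.upper(), "which": which,
                        "fe_deg": fe, "abad_deg": ab, "lar_deg": la,
                    }
                )
        return pd.DataFrame(rows)


def summarize_rom(vg: ViabilityGrid) -> RomSummary:
    """Extreme viable rotation per axis with the companion angles.

    Among poses achieving an extremum, the reported pose minimizes the sum of
    absolute companion angles, breaking remaining ties lexicographically on
    the full triplet.
    """
    poses = vg.viable_poses()
    if len(poses) == 0:
        raise GridError("no viable poses to summarize")
    extrema = {}
    for k, axis in enumerate(RomSummary.AXES):
        others = [i for i in range(3) if i != k]
        for which in ("max", "min"):
            target = poses[:, k].max() if which == "max" else poses[:, k].min()
            at = poses[np.abs(poses[:, k] - target) < 1e-12]
            companion = np.abs(at[:, others]).sum(axis=1)
            best = at[companion == companion.min()]
            order = np.lexsort((best[:, 2], best[:, 1], best[:, 0]))
            extrema[(axis, which)] = tuple(best[order[0]])
    return RomSummary(extrema, vg.n_viable, vg.grid.n_poses)


# ---------------------------------------------------------------------------
# CSV round-trip (columns fe_deg, abad_deg, lar_deg, viable; metadata header)
# ---------------------------------------------------------------------------

def write_viability_csv(vg: ViabilityGrid, path) -> Path:
    path = Path(path)
    g = vg.grid
    meta = [
        f"# joint={vg.joint_name}",
        f"# step_deg={g.step_deg:.10g}",
        f"# fe_range={g.fe_range[0]:.10g},{g.fe_range[1]:.10g}",
        f"# abad_range={g.abad_range[0]:.10g},{g.abad_range[1]:.10g}",
        f"# lar_range={g.lar_range[0]:.10g},{g.lar_range[1]:.10g}",
    ]
    for key, val in vg.provenance.items():
        meta.append(f"# provenance.{key}={val}")
    df = pd.DataFrame(vg.grid.poses(), columns=["fe_deg", "abad_deg", "lar_deg"])
    df["viable"] = vg.viable.astype(int)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text("\n".join(meta) + "\n" + buf.getvalue())
    return path


def read_viability_csv(path) -> ViabilityGrid:
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line.lstrip("# ").partition("=")
        meta[key] = val
    try:
        step = float(meta["step_deg"])
        ranges = {
            k: tuple(float(x) for x in meta[f"{k}_range"].split(","))
            for k in ("fe", "abad", "lar")
        }
    except (KeyError, ValueError) as exc:
        raise GridError(f"malformed viability CSV header in {path}") from exc
    grid = generate_grid(step, ranges["fe"], ranges["abad"], ranges["lar"])
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    if len(df) != grid.n_poses:
        raise GridError(
            f"{path}: {len(df)} rows but header grid implies {grid.n_poses}"
        )
    expected = grid.poses()
    got = df[["fe_deg", "abad_deg", "lar_deg"]].to_numpy(dtype=float)
    if not np.allclose(expected, got, atol=1e-9):
        raise GridError(f"{path}: pose rows disagree with declared grid")
    provenance = {
        k.removeprefix("provenance."): v
        for k, v in meta.items()
        if k.startswith("provenance.")
    }
    return ViabilityGrid(
        grid=grid,
        viable=df["viable"].to_numpy(dtype=int).astype(bool),
        joint_name=meta.get("joint", ""),
        provenance=provenance,
    )
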