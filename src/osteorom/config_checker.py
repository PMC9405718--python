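"""Multi-joint limb-configuration viability checking.

A limb configuration (one Euler pose per joint, 1-3 joints) is viable iff
every configured joint's pose lies within that joint's viable pose space,
represented as an alpha shape over its sampled viable Euler triplets.  The
interactive red/green feedback of the original workflow becomes a
machine-readable :class:`Verdict`.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import OsteoromError, PoseLimitError
from .kinematics import EulerPose, KinematicRig
from .pose_space import AlphaShape, contains
from .rom_sampler import ViabilityGrid

__all__ = ["Verdict", "check_configuration", "batch_check", "cross_validate"]


@dataclass(frozen=True)
class Verdict:
    """Per-joint and overall viability of one limb configuration.

    ``nearest_miss_deg`` maps each inviable joint to the Euclidean distance
    (degrees, uncorrected Euler space) from its pose to the closest vertex of
    its alpha-shape boundary — a reporting convenience, not a metric claim.
    """

    per_joint: dict
    overall: bool
    nearest_miss_deg: dict

    def __post_init__(self) -> None:
        if self.overall != all(self.per_joint.values()):
            raise ValueError("overall flag must be the AND of joint flags")


def _nearest_boundary_vertex(shape: AlphaShape, point: np.ndarray) -> float:
    verts = shape.boundary_mesh.vertices
    if len(verts) == 0:
        return float("nan")
    return float(np.linalg.norm(verts - point, axis=1).min())


def check_configuration(
    rig: KinematicRig, shapes: dict, config: dict
) -> Verdict:
    """Check a 1-3 joint configuration against per-joint alpha shapes.

    Poses outside the hard limits (or the joint's declared limits) raise
    :class:`PoseLimitError` rather than returning a false verdict, because
    such poses were never sampled and their viability is unknown.
    """
    if not 1 <= len(config) <= 3:
        raise OsteoromError("configuration must pose between 1 and 3 joints")
    per_joint: dict[str, bool] = {}
    miss: dict[str, float] = {}
    for name, pose in config.items():
        joint = rig.joint(name)  # KeyError for unknown joints
        if name not in shapes:
            raise OsteoromError(f"no alpha shape supplied for joint {name!r}")
        if not isinstance(pose, EulerPose):
            pose = EulerPose(*pose)  # hard-limit validation happens here
        joint.definition.check_limits(pose)
        inside = contains(shapes[name], pose)
        per_joint[name] = inside
        if not inside:
            miss[name] = _nearest_boundary_vertex(
                shapes[name], pose.as_array()
            )
    return Verdict(
        per_joint=per_joint,
        overall=all(per_joint.values()),
        nearest_miss_deg=miss,
    )


def batch_check(rig: KinematicRig, shapes: dict, config_table) -> pd.DataFrame:
    """Verdicts for a table of configurations, order-preserving.

    ``config_table`` is a DataFrame or CSV path with a ``config_id`` column
    plus ``<joint>_fe_deg`` / ``<joint>_abad_deg`` / ``<joint>_lar_deg``
    columns per posed joint.  Row-level errors are collected in an ``error``
    column instead of aborting the batch.
    """
    if not isinstance(config_table, pd.DataFrame):
        config_table = pd.read_csv(Path(config_table))
    joint_names = sorted(
        {
            c.rsplit("_fe_deg", 1)[0]
            for c in config_table.columns
            if c.endswith("_fe_deg")
        }
    )
    rows = []
    for _, row in config_table.iterrows():
        rec: dict = {"config_id": row.get("config_id", _)}
        try:
            config = {}
            for j in joint_names:
                vals = (
                    row[f"{j}_fe_deg"], row[f"{j}_abad_deg"],
                    row[f"{j}_lar_deg"],
                )
                if any(pd.isna(v) for v in vals):
                    continue  # joint not posed in this row
                config[j] = EulerPose(*(float(v) for v in vals))
            verdict = check_configuration(rig, shapes, config)
            for j, ok in verdict.per_joint.items():
                rec[f"{j}_viable"] = int(ok)
                rec[f"{j}_nearest_miss_deg"] = verdict.nearest_miss_deg.get(
                    j, 0.0
                )
            rec["overall_viable"] = int(verdict.overall)
            rec["error"] = ""
        except (OsteoromError, PoseLimitError, ValueError, KeyError) as exc:
            rec["overall_viable"] = 0
            rec["error"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows)


def cross_validate(
    rig: KinematicRig,
    shapes: dict,
    vg_by_joint: dict,
    n: int,
    seed: int,
) -> dict:
    """Agreement between alpha-shape containment and the recorded collision
    flags, on ``n`` seeded random grid poses per joint.

    Viable poses must always agree at the wrapping radius; inviable poses
    deep inside concavities may not (the alpha shape over-wraps), so the
    fraction is reported, not asserted.  ``n = 0`` returns an empty report.
    """
    if n == 0:
        return {}
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for name, vg in vg_by_joint.items():
        if name not in shapes:
            raise OsteoromError(f"no shape for grid of joint {name!r}")
        if not isinstance(vg, ViabilityGrid):
            raise OsteoromError("vg_by_joint values must be ViabilityGrid")
        idx = rng.integers(0, vg.grid.n_poses, size=n)
        poses = vg.grid.poses()[idx]
        flags = vg.viable[idx]
        verdicts = shapes[name].contains_points(poses)
        out[name] = float((verdicts == flags).mean())
    return out
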