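"""Cross-taxon scaling and limb-configuration transfer.

A source (extant) rig is uniformly scaled so that its hip-to-distal-crus
length matches a target (fossil) rig, aligned at the acetabular ACS, and
reference limb configurations are recovered in the target rig by weighted
landmark least squares.  Scaling is done per knee-spacing option, since the
null-pose crus position depends on the spacing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, OsteoromError
from .geometry import RigidTransform
from .kinematics import (
    ACS,
    EulerPose,
    KinematicRig,
    align_acs,
    forward_kinematics,
)

__all__ = [
    "ScalingSpec",
    "distal_crus_point",
    "scale_to_match",
    "align_models",
    "match_pose",
    "MatchResult",
]


@dataclass(frozen=True)
class ScalingSpec:
    """Uniform scaling that equalizes hip-to-distal-crus lengths."""

    source_length_mm: float
    target_length_mm: float
    scale: float
    knee_option: str = ""

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")


def _acetabular_acs(rig: KinematicRig) -> ACS:
    hip = rig.joints[0]
    return hip.definition.proximal_acs


def _crus_proximal_acs_world(rig: KinematicRig, world: dict) -> ACS:
    knee = rig.joints[-1]
    acs = knee.definition.distal_acs  # in crus-bone frame
    child = knee.child_bones[0]
    return acs.transformed(world[child])


def distal_crus_point(rig: KinematicRig) -> np.ndarray:
    """Distal reference point of the crus in the null pose (world mm).

    Intersection of the crus LAR axis with the plane through the most distal
    vertex of the tibia/fibula pair, the plane taken orthogonal to the LAR
    axis (the projection of the distal extreme onto the axis).
    """
    world = forward_kinematics(rig, {})
    knee = rig.joints[-1]
    acs = _crus_proximal_acs_world(rig, world)
    axis = acs.x_axis
    verts = np.vstack(
        [
            world[name].apply(rig.bones[name].mesh.vertices)
            for name in knee.child_bones
        ]
    )
    proj = (verts - acs.origin) @ axis
    along = proj.max() - proj.min()
    perp = verts - acs.origin - np.outer(proj, axis)
    perp_extent = 2.0 * np.linalg.norm(perp, axis=1).max()
    if along <= perp_extent:
        raise DegenerateGeometryError(
            "crus LAR axis is not the proximodistal direction "
            "(axis-aligned extent does not dominate); distal plane undefined"
        )
    return acs.origin + proj.max() * axis


def hip_to_distal_crus_length(rig: KinematicRig) -> float:
    """Distance from the acetabular ACS origin to the distal crus point."""
    origin = _acetabular_acs(rig).origin  # pelvis is the root frame
    return float(np.linalg.norm(distal_crus_point(rig) - origin))


def scale_to_match(
    source: KinematicRig, target: KinematicRig, knee_option: str = ""
):
    """Uniformly scale the source rig to the target's limb length.

    Returns ``(spec, scaled_source)``; the source passed in is not mutated.
    The two hip-to-distal-crus lengths agree within 1e-6 relative after
    scaling.
    """
    ls = hip_to_distal_crus_length(source)
    lt = hip_to_distal_crus_length(target)
    if ls <= 0:
        raise OsteoromError("source hip-to-distal-crus length is zero")
    scale = lt / ls
    spec = ScalingSpec(
        source_length_mm=ls,
        target_length_mm=lt,
        scale=scale,
        knee_option=knee_option,
    )
    return spec, source.scaled(scale)


def align_models(source: KinematicRig, target: KinematicRig) -> RigidTransform:
    """Transform mapping the source acetabular ACS onto the target's
    (point-and-orient constraint)."""
    return align_acs(_acetabular_acs(source), _acetabular_acs(target))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a landmark-based pose match."""

    configuration: dict
    residual: float  # weighted sum of squared landmark distances (mm^2)
    converged: bool


def pose_residual(
    rig: KinematicRig,
    config: dict,
    landmarks_local: dict,
    landmarks_world: dict,
    weights: dict,
) -> float:
    """Weighted sum of squared distances, recomputed from scratch."""
    world = forward_kinematics(rig, config, check_limits=False)
    total = 0.0
    for bone, local in landmarks_local.items():
        posed = world[bone].apply(np.asarray(local, float))
        diff = posed - np.asarray(landmarks_world[bone], float)
        total += weights.get(bone, 1.0) * float((diff ** 2).sum())
    return total


def match_pose(
    rig: KinematicRig,
    landmarks_local: dict,
    landmarks_world: dict,
    weights: dict | None = None,
    x0: np.ndarray | None = None,
) -> MatchResult:
    """Recover the limb configuration best matching reference landmarks.

    ``landmarks_local`` maps bone -> (k, 3) points in that bone's frame;
    ``landmarks_world`` the corresponding target positions.  Distal segments
    (bones beyond the first joint's children) default to weight 10, encoding
    the priority on aligning distal articular surfaces.  Minimization is
    bounded trust-region least squares over the joint Euler angles starting
    at the null pose; deterministic.
    """
    if not landmarks_local:
        raise OsteoromError("no landmarks supplied")
    for bone, pts in landmarks_local.items():
        pts = np.asarray(pts, float)
        if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(0)) < 2:
            raise OsteoromError(
                f"bone {bone!r}: need >= 3 non-collinear landmarks"
            )
        if bone not in landmarks_world:
            raise OsteoromError(f"bone {bone!r}: no target landmarks")
    if weights is None:
        proximal = set(rig.joints[0].child_bones) | {rig.root}
        weights = {
            b: (1.0 if b in proximal else 10.0) for b in landmarks_local
        }
    joints = rig.joint_names
    lo, hi = [], []
    for name in joints:
        lim = rig.joint(name).definition.limits
        for key in ("fe", "abad", "lar"):
            lo.append(lim[key][0])
            hi.append(lim[key][1])

    def unpack(x: np.ndarray) -> dict:
        return {
            name: EulerPose(*x[3 * i:3 * i + 3])
            for i, name in enumerate(joints)
        }

    def residuals(x: np.ndarray) -> np.ndarray:
        world = forward_kinematics(rig, unpack(x), check_limits=False)
        res = []
        for bone, local in landmarks_local.items():
            posed = world[bone].apply(np.asarray(local, float))
            diff = posed - np.asarray(landmarks_world[bone], float)
            res.append(np.sqrt(weights.get(bone, 1.0)) * diff.ravel())
        return np.concatenate(res)

    if x0 is None:
        x0 = np.zeros(3 * len(joints))
    fit = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12,
        gtol=1e-12,
    )
    config = unpack(fit.x)
    residual = pose_residual(
        rig, config, landmarks_local, landmarks_world, weights
    )
    return MatchResult(
        configuration=config, residual=residual, converged=bool(fit.success)
    )
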