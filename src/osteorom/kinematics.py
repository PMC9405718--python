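"""Anatomical coordinate systems, Euler convention, joints, and forward
kinematics of a pelvis-femur-crus chain.

Convention
----------
Joint rotations are intrinsic Z-Y-X Euler angles in degrees:
flexion-extension (FE) about Z first, then abduction-adduction (ABAD) about
Y, then long-axis rotation (LAR) about X, i.e. ``R = Rz(fe) @ Ry(abad) @
Rx(lar)``.  Positive FE is flexion, positive ABAD abduction, positive LAR
external rotation.  Hard limits are FE, LAR in [-180, 180] and ABAD in
[-90, 90]; ABAD = +/-90 (gimbal lock) is permitted because poses are
compared as Euler triplets, not orientations.

In the null pose (all angles zero) the femur extends laterally (+X of the
acetabular ACS) and the knee is extended.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, PoseLimitError
from .geometry import RigidTransform, TriMesh

__all__ = [
    "ACS",
    "EulerPose",
    "JointDefinition",
    "Bone",
    "KinematicRig",
    "HARD_LIMITS",
    "euler_to_matrix",
    "align_acs",
    "rotate_acs_about_lar",
    "build_hip_joint",
    "build_hinge_knee",
    "relative_spacing_from_reference",
    "joint_child_transform",
    "forward_kinematics",
    "read_configuration",
    "write_configuration",
]

#: Hard rotation limits (degrees) preventing redundant Euler poses.
HARD_LIMITS = {"fe": (-180.0, 180.0), "abad": (-90.0, 90.0),
               "lar": (-180.0, 180.0)}


@dataclass(frozen=True)
class ACS:
    """Anatomical coordinate system: origin plus right-handed orthonormal
    axes.  X is the LAR axis (lateral), Y the ABAD axis (posterior), Z the
    FE axis (ventral)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(
                self, name,
                np.asarray(getattr(self, name), dtype=np.float64).reshape(3),
            )
        m = self.matrix
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("ACS axes not orthonormal")
        if not np.allclose(
            np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-9
        ):
            raise DegenerateGeometryError("ACS axes not right-handed")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with the axes as columns (local -> parent rotation)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @classmethod
    def from_matrix(cls, origin, matrix) -> "ACS":
        m = np.asarray(matrix, dtype=np.float64)
        return cls(origin, m[:, 0], m[:, 1], m[:, 2])

    @classmethod
    def standard(cls, origin=(0.0, 0.0, 0.0)) -> "ACS":
        return cls(origin, (1, 0, 0), (0, 1, 0), (0, 0, 1))

    def transformed(self, xf: RigidTransform) -> "ACS":
        return ACS.from_matrix(
            xf.apply(self.origin), xf.rotation @ self.matrix
        )


@dataclass(frozen=True)
class EulerPose:
    """(FE, ABAD, LAR) rotation triplet in degrees."""

    fe_deg: float = 0.0
    abad_deg: float = 0.0
    lar_deg: float = 0.0

    def __post_init__(self) -> None:
        for name, key in (
            ("fe_deg", "fe"), ("abad_deg", "abad"), ("lar_deg", "lar")
        ):
            val = float(getattr(self, name))
            object.__setattr__(self, name, val)
            lo, hi = HARD_LIMITS[key]
            if not (lo <= val <= hi):
                raise PoseLimitError(
                    f"{name}={val} outside hard limits [{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.fe_deg, self.abad_deg, self.lar_deg])


def euler_to_matrix(pose: EulerPose) -> np.ndarray:
    """Rotation matrix Rz(fe) @ Ry(abad) @ Rx(lar) (intrinsic Z-Y-X)."""
    fe, ab, la = np.deg2rad(pose.as_array())
    cf, sf = np.cos(fe), np.sin(fe)
    ca, sa = np.cos(ab), np.sin(ab)
    cl, sl = np.cos(la), np.sin(la)
    rz = np.array([[cf, -sf, 0.0], [sf, cf, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cl, -sl], [0.0, sl, cl]])
    return rz @ ry @ rx


def euler_matrices(poses: np.ndarray) -> np.ndarray:
    """Vectorized Rz@Ry@Rx for an (n, 3) array of (fe, abad, lar) degrees."""
    ang = np.deg2rad(np.asarray(poses, dtype=np.float64))
    cf, sf = np.cos(ang[:, 0]), np.sin(ang[:, 0])
    ca, sa = np.cos(ang[:, 1]), np.sin(ang[:, 1])
    cl, sl = np.cos(ang[:, 2]), np.sin(ang[:, 2])
    out = np.empty((len(ang), 3, 3))
    out[:, 0, 0] = cf * ca
    out[:, 0, 1] = cf * sa * sl - sf * cl
    out[:, 0, 2] = cf * sa * cl + sf * sl
    out[:, 1, 0] = sf * ca
    out[:, 1, 1] = sf * sa * sl + cf * cl
    out[:, 1, 2] = sf * sa * cl - cf * sl
    out[:, 2, 0] = -sa
    out[:, 2, 1] = ca * sl
    out[:, 2, 2] = ca * cl
    return out


def align_acs(moving: ACS, target: ACS) -> RigidTransform:
    """Rigid transform mapping ``moving`` exactly onto ``target`` (the
    point-and-orient constraint)."""
    rot = target.matrix @ moving.matrix.T
    return RigidTransform(rot, target.origin - rot @ moving.origin)


def rotate_acs_about_lar(acs: ACS, angle_deg: float) -> ACS:
    """Rotate the Y/Z axes about the ACS's own X (LAR) axis, right-handed.

    Used to correct for femoral torsion differences between taxa; the origin
    is unchanged and right-handedness is preserved.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    y = c * acs.y_axis + s * acs.z_axis
    z = -s * acs.y_axis + c * acs.z_axis
    return ACS(acs.origin, acs.x_axis, y, z)


@dataclass(frozen=True)
class JointDefinition:
    """A rotational joint between a parent (proximal) and child (distal) bone.

    The double-joint rig is modelled as a fixed translational ``spacing_offset``
    (mm, in proximal-ACS coordinates, the position joint) followed by the Euler
    rotation (the rotation joint).  ``rotation_center_mode`` places the
    rotation center along the offset: at the proximal ACS origin, midway
    between the two ACS origins, or at the offset distal ACS origin.
    """

    name: str
    proximal_acs: ACS
    distal_acs: ACS
    spacing_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    rotation_center_mode: str = "midway"
    limits: dict = field(default_factory=lambda: dict(HARD_LIMITS))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "spacing_offset",
            np.asarray(self.spacing_offset, dtype=np.float64).reshape(3),
        )
        if not np.all(np.isfinite(self.spacing_offset)):
            raise ValueError("spacing_offset must be finite")
        if self.rotation_center_mode not in (
            "at_proximal", "midway", "at_distal"
        ):
            raise ValueError(
                f"unknown rotation_center_mode {self.rotation_center_mode!r}"
            )
        for key, (lo, hi) in self.limits.items():
            hlo, hhi = HARD_LIMITS[key]
            if lo < hlo or hi > hhi:
                raise ValueError(f"{key} limits exceed hard limits")

    @property
    def center_fraction(self) -> float:
        return {"at_proximal": 0.0, "midway": 0.5, "at_distal": 1.0}[
            self.rotation_center_mode
        ]

    def rotation_center(self) -> np.ndarray:
        """Rotation center in the parent bone's frame."""
        return self.proximal_acs.origin + self.proximal_acs.matrix @ (
            self.center_fraction * self.spacing_offset
        )

    def check_limits(self, pose: EulerPose) -> None:
        for key, val in (
            ("fe", pose.fe_deg), ("abad", pose.abad_deg), ("lar", pose.lar_deg)
        ):
            lo, hi = self.limits.get(key, HARD_LIMITS[key])
            if not (lo <= val <= hi):
                raise PoseLimitError(
                    f"joint {self.name}: {key}={val} outside [{lo}, {hi}]"
                )


def build_hip_joint(
    acetabular_acs: ACS,
    femoral_acs: ACS,
    cartilage_offset=(0.0, 0.0, 0.0),
    name: str = "hip",
) -> JointDefinition:
    """Ball-joint definition with a cartilage-space translation.

    ``cartilage_offset`` is expressed in acetabular-ACS coordinates (e.g.
    +X lateral, -Z dorsal); the rotation center sits midway between the
    acetabular origin and the offset femoral origin, with joint axes aligned
    to the ACS axes in the null pose.
    """
    return JointDefinition(
        name=name,
        proximal_acs=acetabular_acs,
        distal_acs=femoral_acs,
        spacing_offset=np.asarray(cartilage_offset, dtype=float),
        rotation_center_mode="midway",
    )


def build_hinge_knee(
    distal_femoral_acs: ACS,
    proximal_crus_acs: ACS,
    spacing_mm: float,
    calibration_fe_deg: float = 45.0,
    name: str = "knee",
) -> JointDefinition:
    """Hinge-knee definition with fixed joint spacing along local X.

    The prism-based hinge is approximated by a constant translation offset
    calibrated at ``calibration_fe_deg`` flexion (45 degrees by default, the
    objective mid-flexion calibration pose); because the offset is fixed in
    the parent ACS frame, the null-pose ACS-to-ACS distance along local X
    equals ``spacing_mm`` at every flexion angle.
    """
    if not spacing_mm > 0:
        raise ValueError("spacing must be positive")
    if not np.isfinite(calibration_fe_deg):
        raise ValueError("calibration angle must be finite")
    return JointDefinition(
        name=name,
        proximal_acs=distal_femoral_acs,
        distal_acs=proximal_crus_acs,
        spacing_offset=np.array([float(spacing_mm), 0.0, 0.0]),
        rotation_center_mode="midway",
    )


def relative_spacing_from_reference(
    reference_tibia_length_mm: float, fraction: float = 0.26
) -> float:
    """Joint spacing as a fraction of a reference tibial length (the
    26%-of-tibia rule for transferring relative joint spacing)."""
    if reference_tibia_length_mm <= 0:
        raise ValueError("tibia length must be positive")
    return float(fraction) * float(reference_tibia_length_mm)


def joint_child_transform(
    joint: JointDefinition, pose: EulerPose, check_limits: bool = True
) -> RigidTransform:
    """Child-bone-frame -> parent-bone-frame transform for one joint pose.

    v_parent = o_p + A_p @ (t*off + R(pose) @ ((1-t)*off + A_d.T @ (v - o_d)))
    with t the rotation-center fraction, off the spacing offset, A/o the ACS
    matrix/origin.
    """
    if check_limits:
        joint.check_limits(pose)
    ap = joint.proximal_acs.matrix
    op = joint.proximal_acs.origin
    ad = joint.distal_acs.matrix
    od = joint.distal_acs.origin
    t = joint.center_fraction
    off = joint.spacing_offset
    re = euler_to_matrix(pose)
    rot = ap @ re @ ad.T
    trans = op + ap @ (t * off + re @ ((1.0 - t) * off)) - rot @ od
    return RigidTransform(rot, trans)


@dataclass
class Bone:
    """A rigid skeletal element: mesh plus its named local ACSs."""

    name: str
    mesh: TriMesh
    acs: dict = field(default_factory=dict)


@dataclass
class Joint:
    """Placement of a JointDefinition within a rig tree."""

    definition: JointDefinition
    parent_bone: str
    child_bones: tuple

    @property
    def name(self) -> str:
        return self.definition.name


@dataclass
class KinematicRig:
    """A tree of bones rooted at the pelvis, linked by rotational joints.

    ``joints`` are ordered proximal-to-distal; each joint's definition lives
    in its parent bone's frame (proximal ACS) and child bone frame (distal
    ACS).  Multiple child bones (tibia + fibula as the crus unit) share one
    joint transform.
    """

    bones: dict
    joints: list
    root: str

    def __post_init__(self) -> None:
        if self.root not in self.bones:
            raise ValueError(f"root bone {self.root!r} missing")
        parents = {self.root}
        for joint in self.joints:
            if joint.parent_bone not in parents:
                raise ValueError(
                    f"joint {joint.name!r}: parent {joint.parent_bone!r} is "
                    "not reachable from the root (chain must be a tree)"
                )
            for child in joint.child_bones:
                if child not in self.bones:
                    raise ValueError(f"unknown child bone {child!r}")
                parents.add(child)

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"no joint named {name!r}")

    @property
    def joint_names(self) -> list:
        return [j.name for j in self.joints]

    def copy(self) -> "KinematicRig":
        bones = {
            k: Bone(b.name, b.mesh.copy(), dict(b.acs))
            for k, b in self.bones.items()
        }
        return KinematicRig(bones, list(self.joints), self.root)

    def scaled(self, factor: float) -> "KinematicRig":
        """Uniformly scale all geometry (meshes, ACS origins, spacings)."""
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        xf = RigidTransform(np.eye(3), np.zeros(3), float(factor))
        bones = {}
        for k, b in self.bones.items():
            acs = {n: a.transformed(xf) for n, a in b.acs.items()}
            mesh = TriMesh(b.mesh.vertices * factor, b.mesh.faces, b.mesh.name)
            bones[k] = Bone(b.name, mesh, acs)
        joints = []
        for j in self.joints:
            d = j.definition
            new_def = replace(
                d,
                proximal_acs=d.proximal_acs.transformed(xf),
                distal_acs=d.distal_acs.transformed(xf),
                spacing_offset=d.spacing_offset * factor,
            )
            joints.append(Joint(new_def, j.parent_bone, j.child_bones))
        return KinematicRig(bones, joints, self.root)


def forward_kinematics(
    rig: KinematicRig, config: dict, check_limits: bool = True
) -> dict:
    """World transform per bone for a limb configuration.

    ``config`` maps joint name -> EulerPose; unspecified joints stay at the
    null pose.  The root bone sits at the identity (root frame); each child
    bone's transform is its parent's composed with the joint transform.
    """
    for name in config:
        rig.joint(name)  # raises KeyError on unknown joints
    world = {rig.root: RigidTransform.identity()}
    for joint in rig.joints:
        pose = config.get(joint.name, EulerPose())
        local = joint_child_transform(
            joint.definition, pose, check_limits=check_limits
        )
        parent_xf = world[joint.parent_bone]
        child_xf = parent_xf.compose(local)
        for child in joint.child_bones:
            world[child] = child_xf
    return world


# ---------------------------------------------------------------------------
# Limb-configuration files (CSV/JSON, columns joint, fe_deg, abad_deg, lar_deg)
# ---------------------------------------------------------------------------

def read_configuration(path) -> dict:
    """Read one limb configuration: map joint -> EulerPose."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {
            k: EulerPose(*[float(x) for x in v]) for k, v in raw.items()
        }
    df = pd.read_csv(path)
    required = {"joint", "fe_deg", "abad_deg", "lar_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"configuration file needs columns {sorted(required)}")
    return {
        str(r.joint): EulerPose(r.fe_deg, r.abad_deg, r.lar_deg)
        for r in df.itertuples()
    }


def write_configuration(config: dict, path) -> Path:
    path = Path(path)
    rows = [
        {
            "joint": k, "fe_deg": p.fe_deg, "abad_deg": p.abad_deg,
            "lar_deg": p.lar_deg,
        }
        for k, p in config.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
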