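"""Synthetic articulating joints with analytically known viable pose spaces.

These parametric "bones" stand in for fossil photogrammetry meshes: their
geometry is chosen so that the bone-on-bone collision boundary has a closed
form, giving an exact oracle for the grid sampler.

Socket joint
------------
The proximal element is a spherical shell cup: material occupying
``{r_inner <= |p| <= r_outer, polar(p) >= rim}`` with the polar angle
measured from the +X (lateral) axis, so the cup opens toward +X with rim
half-angle ``cup_rim_half_angle``.  The distal element is a neck cylinder of
radius ``neck_radius`` extending from the joint center along its local +X
axis (the femoral head itself is omitted: with positive clearance it can
never touch the cup, so it would only slow the collision test without
changing the answer).  Rotating the neck by (FE, ABAD, LAR) tilts its axis
to ``u = R @ ex`` with excursion ``theta = acos(cos fe * cos abad)`` from
the cup axis; the cylinder surface at distance ``r`` from the center spans
polar angles ``theta +/- asin(neck_radius / r)``, widest at the cup's inner
radius.  Hence the exact viability condition::

    theta <= rim - asin(neck_radius / r_inner)        (LAR-free)

Hinge joint
-----------
The distal element is a rectangular bar (length ``bar_length`` along +X,
half-width ``bar_half_width`` in Y, half-height ``bar_half_height`` in Z).
The proximal element has two independent parts: a tall C-ring around the Z
axis whose opening arc is ``trough_arc`` (the FE stops), and a pair of
full-disk clearance plates at ``|z| >= plate_gap`` (the ABAD/LAR stops).
With ``R = Rz(fe) Ry(ab) Rx(lar)``, the bar's maximum |z| is
``L |sin ab| + |cos ab| (w |sin lar| + b |cos lar|)`` and its azimuthal
half-width at radius ``rho`` is ``asin((w |cos lar| + b |sin lar|) / rho)``
(both exact for a box), giving the exact collision predicate::

    plate:  L |sin ab| + |cos ab| (w |sin lar| + b |cos lar|)  >  gap
    ring:   |fe| + asin((w |cos lar| + b |sin lar|) / ring_inner) > arc/2
    viable  iff  neither holds

Note the axes couple: the ABAD and LAR thresholds trade off through the
plate term, and the FE stop tightens as |LAR| grows.  Per-axis stop values
are derived from this closed form by 1-D scans, not assumed separable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TriMesh
from .kinematics import ACS, Bone, EulerPose, Joint, JointDefinition, \
    KinematicRig, build_hinge_knee, build_hip_joint
from .primitives import (
    concatenate_meshes,
    make_annular_sector_prism,
    make_box,
    make_cylinder,
    make_spherical_shell_cap,
)

__all__ = [
    "SocketJointSpec",
    "HingeJointSpec",
    "ToyLimbSpec",
    "SocketPredicate",
    "HingePredicate",
    "make_socket_joint",
    "make_hinge_joint",
    "make_toy_limb",
    "ERYOPS_RATIOS",
    "SALAMANDER_RATIOS",
]

#: femur:pelvis, tibia:femur, fibula:tibia proximodistal length ratios
ERYOPS_RATIOS = (0.92, 0.62, 0.98)
SALAMANDER_RATIOS = (0.62, 0.57, 0.85)


@dataclass(frozen=True)
class SocketJointSpec:
    """Ball-in-cup joint with a cone of free excursion.

    ``cup_rim_half_angle`` is the polar angle of the cup rim from the cup
    axis; ``clearance`` is the radial gap between head and cup standing in
    for cartilage.  Default dimensions give a neck angular half-width of
    ``asin(0.5/10) ~ 2.87 deg``, keeping 5-degree grid samples well clear of
    the viability threshold relative to mesh discretization error.
    """

    cup_rim_half_angle: float = 60.0
    head_radius: float = 9.5
    clearance: float = 0.5
    cup_thickness: float = 2.0
    neck_length: float = 16.0
    neck_radius: float = 0.5
    n_azimuth: int = 32
    n_polar: int = 12
    n_cylinder: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cup_rim_half_angle < 90.0:
            raise ValueError("rim half-angle must be in (0, 90) degrees")
        if self.clearance < 0:
            raise ValueError("clearance must be non-negative")
        if self.neck_radius >= self.cup_inner_radius:
            raise ValueError("neck thicker than the cup opening")
        if self.neck_length <= self.cup_outer_radius:
            raise ValueError("neck must extend beyond the cup")

    @property
    def cup_inner_radius(self) -> float:
        return self.head_radius + self.clearance

    @property
    def cup_outer_radius(self) -> float:
        return self.cup_inner_radius + self.cup_thickness


class SocketPredicate:
    """Closed-form viability for a socket joint: pure function of the pose."""

    def __init__(self, spec: SocketJointSpec) -> None:
        self.spec = spec
        self.neck_half_width_deg = float(
            np.rad2deg(np.arcsin(spec.neck_radius / spec.cup_inner_radius))
        )
        #: maximum viable excursion of the neck axis from the cup axis
        self.threshold_deg = spec.cup_rim_half_angle - self.neck_half_width_deg

    @staticmethod
    def excursion_deg(pose) -> float:
        """Angle between the rotated neck axis and the cup (+X) axis."""
        fe, ab, _ = np.deg2rad(np.asarray(_pose_array(pose)))
        c = np.clip(np.cos(fe) * np.cos(ab), -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))

    def __call__(self, pose) -> bool:
        return self.excursion_deg(pose) <= self.threshold_deg

    def batch(self, poses: np.ndarray) -> np.ndarray:
        ang = np.deg2rad(np.asarray(poses, float))
        c = np.clip(np.cos(ang[:, 0]) * np.cos(ang[:, 1]), -1.0, 1.0)
        return np.rad2deg(np.arccos(c)) <= self.threshold_deg


def _pose_array(pose):
    if isinstance(pose, EulerPose):
        return pose.as_array()
    return np.asarray(pose, dtype=float).reshape(3)


def make_socket_joint(spec: SocketJointSpec | None = None):
    """Build (proximal cup, distal neck, joint, analytic predicate)."""
    if spec is None:
        spec = SocketJointSpec()
    cup = make_spherical_shell_cap(
        spec.cup_inner_radius,
        spec.cup_outer_radius,
        spec.cup_rim_half_angle,
        n_azimuth=spec.n_azimuth,
        n_polar=spec.n_polar,
        name="socket_cup",
    )
    neck = make_cylinder(
        spec.neck_radius, 0.0, spec.neck_length, n_azimuth=spec.n_cylinder,
        axis="x", name="socket_neck",
    )
    joint = build_hip_joint(
        ACS.standard(), ACS.standard(), cartilage_offset=(0.0, 0.0, 0.0),
        name="socket",
    )
    return cup, neck, joint, SocketPredicate(spec)


@dataclass(frozen=True)
class HingeJointSpec:
    """Bar-in-trough hinge with clearance plates.

    Default thresholds (exact closed form): FE stop ~36.4 deg at zero LAR,
    ABAD threshold ~8.2 deg at zero LAR, LAR threshold ~54.7 deg at zero
    ABAD.  ``plate_gap`` must be smaller than ``bar_half_width`` so the
    inviable LAR band, once entered, stays closed through +/-90 deg (the
    bar's z-extent w*sin|lar| + b*cos|lar| peaks between its two ends); grid
    samples at 5/15 degree steps then sit clear of every collision boundary
    by far more than mesh discretization error.
    """

    trough_arc: float = 120.0
    spacing: float = 0.0
    bar_length: float = 12.0
    bar_half_width: float = 2.4
    bar_half_height: float = 0.6
    plate_gap: float = 2.3
    ring_inner: float = 6.0
    ring_outer: float = 9.0
    ring_half_height: float = 16.0
    plate_thickness: float = 6.0
    plate_radius: float = 16.0
    n_azimuth: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.trough_arc <= 360.0:
            raise ValueError("trough arc must be in (0, 360] degrees")
        if self.spacing < 0:
            raise ValueError("spacing must be non-negative")
        cross = np.hypot(self.bar_half_width, self.bar_half_height)
        if self.bar_half_height >= self.plate_gap:
            raise ValueError(
                "bar must clear the plates at the null pose (b < gap)"
            )
        if self.spacing + cross >= self.ring_inner:
            raise ValueError("bar root must stay inside the ring opening")
        if self.tip_reach <= self.ring_outer:
            raise ValueError("bar must pass through the ring radially")
        if self.bar_half_width >= self.ring_inner:
            raise ValueError("bar wider than the ring opening")

    @property
    def tip_reach(self) -> float:
        return self.spacing + self.bar_length


class HingePredicate:
    """Closed-form viability for the hinge fixture (see module docstring)."""

    def __init__(self, spec: HingeJointSpec) -> None:
        self.spec = spec

    def _terms(self, poses: np.ndarray):
        s = self.spec
        ang = np.deg2rad(np.asarray(poses, float))
        fe = np.asarray(poses, float)[..., 0]
        sa, ca = np.abs(np.sin(ang[..., 1])), np.abs(np.cos(ang[..., 1]))
        sl, cl = np.abs(np.sin(ang[..., 2])), np.abs(np.cos(ang[..., 2]))
        z_extent = s.tip_reach * sa + ca * (
            s.bar_half_width * sl + s.bar_half_height * cl
        )
        h_perp = s.bar_half_width * cl + s.bar_half_height * sl
        half_width_deg = np.rad2deg(
            np.arcsin(np.minimum(1.0, h_perp / s.ring_inner))
        )
        plate_hit = z_extent > s.plate_gap
        if s.trough_arc >= 360.0:  # no ring is built: FE unrestricted
            ring_hit = np.zeros_like(plate_hit)
        else:
            ring_hit = np.abs(fe) + half_width_deg > s.trough_arc / 2.0
        return plate_hit, ring_hit

    def __call__(self, pose) -> bool:
        plate, ring = self._terms(_pose_array(pose)[None, :])
        return not bool(plate[0] or ring[0])

    def batch(self, poses: np.ndarray) -> np.ndarray:
        plate, ring = self._terms(poses)
        return ~(plate | ring)

    def fe_stop_deg(self, lar_deg: float = 0.0) -> float:
        """FE stop (degrees) at a given LAR, from the ring term."""
        s = self.spec
        la = np.deg2rad(lar_deg)
        h = s.bar_half_width * abs(np.cos(la)) + s.bar_half_height * abs(
            np.sin(la)
        )
        return s.trough_arc / 2.0 - float(
            np.rad2deg(np.arcsin(min(1.0, h / s.ring_inner)))
        )

    def abad_threshold_deg(self, lar_deg: float = 0.0) -> float:
        """|ABAD| threshold at a given LAR, from the plate term (1-D solve)."""
        s = self.spec
        la = np.deg2rad(lar_deg)
        c = s.bar_half_width * abs(np.sin(la)) + s.bar_half_height * abs(
            np.cos(la)
        )
        # solve L sin a + c cos a = gap for a in [0, 90]
        amp = np.hypot(s.tip_reach, c)
        phase = np.arctan2(c, s.tip_reach)
        if s.plate_gap >= amp:
            return 90.0
        return float(np.rad2deg(np.arcsin(s.plate_gap / amp) - phase))

    def lar_threshold_deg(self, abad_deg: float = 0.0) -> float:
        """|LAR| threshold at a given ABAD, scanned from the closed form."""
        lar = np.arange(0.0, 180.0001, 0.01)
        poses = np.column_stack(
            [np.zeros_like(lar), np.full_like(lar, abad_deg), lar]
        )
        ok = self.batch(poses)
        if not ok[0]:
            return 0.0
        first_bad = np.argmin(ok) if not ok.all() else len(ok)
        return float(lar[first_bad - 1])


def make_hinge_joint(spec: HingeJointSpec | None = None):
    """Build (proximal trough+plates, distal bar, joint, predicate)."""
    if spec is None:
        spec = HingeJointSpec()
    s = spec
    half_arc = s.trough_arc / 2.0
    parts = []
    if s.trough_arc < 360.0:
        parts.append(
            make_annular_sector_prism(
                s.ring_inner, s.ring_outer,
                -s.ring_half_height, s.ring_half_height,
                half_arc, 360.0 - half_arc,
                n_azimuth=s.n_azimuth, name="hinge_ring",
            )
        )
    parts.append(
        make_cylinder(
            s.plate_radius, s.plate_gap, s.plate_gap + s.plate_thickness,
            n_azimuth=s.n_azimuth, axis="z", name="hinge_plate_top",
        )
    )
    parts.append(
        make_cylinder(
            s.plate_radius, -s.plate_gap - s.plate_thickness, -s.plate_gap,
            n_azimuth=s.n_azimuth, axis="z", name="hinge_plate_bottom",
        )
    )
    trough = concatenate_meshes(parts, name="hinge_trough")
    bar = make_box(
        (s.bar_length / 2.0, s.bar_half_width, s.bar_half_height),
        center=(s.spacing + s.bar_length / 2.0, 0.0, 0.0),
        name="hinge_bar",
    )
    # the spacing offset is baked into the bar mesh (the bar spans
    # [spacing, spacing + length] along X) so that the rotation center stays
    # at the trough center, where the closed form is derived
    joint = JointDefinition(
        name="hinge", proximal_acs=ACS.standard(),
        distal_acs=ACS.standard(), spacing_offset=np.zeros(3),
        rotation_center_mode="at_proximal",
    )
    return trough, bar, joint, HingePredicate(spec)


@dataclass(frozen=True)
class ToyLimbSpec:
    """Toy pelvis-femur-crus rig with prescribed segment length ratios."""

    pelvis_length: float = 100.0
    femur_pelvis_ratio: float = ERYOPS_RATIOS[0]
    tibia_femur_ratio: float = ERYOPS_RATIOS[1]
    fibula_tibia_ratio: float = ERYOPS_RATIOS[2]
    knee_spacing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for val in (
            self.pelvis_length, self.femur_pelvis_ratio,
            self.tibia_femur_ratio, self.fibula_tibia_ratio,
            self.knee_spacing,
        ):
            if not val > 0:
                raise ValueError("toy limb parameters must be positive")

    @property
    def femur_length(self) -> float:
        return self.pelvis_length * self.femur_pelvis_ratio

    @property
    def tibia_length(self) -> float:
        return self.femur_length * self.tibia_femur_ratio

    @property
    def fibula_length(self) -> float:
        return self.tibia_length * self.fibula_tibia_ratio


def make_toy_limb(spec: ToyLimbSpec | None = None) -> KinematicRig:
    """Deterministic toy rig: box pelvis, cylinder femur and crus bones.

    The null pose extends the femur laterally (+X) from the acetabulum with
    the knee extended, so the proximodistal axis of every limb segment is its
    local +X axis.  Proximodistal lengths follow the spec ratios exactly at
    mesh level (cylinders span [0, L] along X); the pelvis length is its
    anteroposterior (Y) extent.
    """
    if spec is None:
        spec = ToyLimbSpec()
    hip_point = np.array([6.0, 0.0, 0.0])
    pelvis = make_box(
        (6.0, spec.pelvis_length / 2.0, 10.0), center=(0.0, 0.0, 0.0),
        name="pelvis",
    )
    femur_r = max(1.5, 0.03 * spec.femur_length)
    femur = make_cylinder(
        femur_r, 0.0, spec.femur_length, n_azimuth=16, axis="x", name="femur"
    )
    crus_r = 0.6 * femur_r
    tibia = make_cylinder(
        crus_r, 0.0, spec.tibia_length, n_azimuth=16, axis="x", name="tibia"
    )
    fib = make_cylinder(
        crus_r, 0.0, spec.fibula_length, n_azimuth=16, axis="x", name="fibula"
    )
    fib = TriMesh(
        fib.vertices + np.array([0.0, 3.0 * crus_r, 0.0]), fib.faces, "fibula"
    )

    acet_acs = ACS.standard(origin=hip_point)
    femoral_head_acs = ACS.standard(origin=(0.0, 0.0, 0.0))
    hip = build_hip_joint(
        acet_acs, femoral_head_acs, cartilage_offset=(2.0, 0.0, 0.0),
        name="hip",
    )
    distal_femoral_acs = ACS.standard(origin=(spec.femur_length, 0.0, 0.0))
    crus_prox_acs = ACS.standard(origin=(0.0, 0.0, 0.0))
    knee = build_hinge_knee(
        distal_femoral_acs, crus_prox_acs, spacing_mm=spec.knee_spacing,
        name="knee",
    )
    bones = {
        "pelvis": Bone("pelvis", pelvis, {"acetabular": acet_acs}),
        "femur": Bone(
            "femur", femur,
            {"proximal": femoral_head_acs, "distal": distal_femoral_acs},
        ),
        "tibia": Bone("tibia", tibia, {"proximal": crus_prox_acs}),
        "fibula": Bone("fibula", fib, {"proximal": crus_prox_acs}),
    }
    joints = [
        Joint(hip, "pelvis", ("femur",)),
        Joint(knee, "femur", ("tibia", "fibula")),
    ]
    return KinematicRig(bones=bones, joints=joints, root="pelvis")
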