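"""Euler convention, ACS operations, joint builders, forward kinematics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteorom.errors import DegenerateGeometryError, PoseLimitError
from osteorom.geometry import RigidTransform
from osteorom.kinematics import (
    ACS,
    Bone,
    EulerPose,
    Joint,
    JointDefinition,
    KinematicRig,
    align_acs,
    build_hinge_knee,
    build_hip_joint,
    euler_to_matrix,
    forward_kinematics,
    joint_child_transform,
    relative_spacing_from_reference,
    rotate_acs_about_lar,
)
from osteorom.primitives import make_box

from oracles import elementary_euler_product

angle = st.floats(-180, 180, allow_nan=False)
abad_angle = st.floats(-90, 90, allow_nan=False)


class TestEulerToMatrix:
    def test_zero_is_identity(self):
        np.testing.assert_allclose(
            euler_to_matrix(EulerPose()), np.eye(3), atol=1e-12
        )

    def test_pure_flexion_rotates_about_z(self):
        out = euler_to_matrix(EulerPose(90, 0, 0)) @ np.array([1.0, 0, 0])
        np.testing.assert_allclose(out, [0, 1, 0], atol=1e-12)

    @given(fe=angle, ab=abad_angle, la=angle)
    @settings(max_examples=50, deadline=None)
    def test_matches_elementary_product(self, fe, ab, la):
        got = euler_to_matrix(EulerPose(fe, ab, la))
        want = elementary_euler_product(fe, ab, la)
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert np.linalg.det(got) == pytest.approx(1.0)

    def test_out_of_bounds_pose_rejected(self):
        with pytest.raises(PoseLimitError):
            EulerPose(190, 0, 0)
        with pytest.raises(PoseLimitError):
            EulerPose(0, 91, 0)


class TestACS:
    def test_non_orthonormal_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ACS((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 0, 1))

    def test_left_handed_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ACS((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, -1))

    def test_align_to_self_is_identity(self):
        a = ACS.standard((1, 2, 3))
        xf = align_acs(a, a)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, 0, atol=1e-12)

    def test_align_translated_copy(self):
        a = ACS.standard((0, 0, 0))
        b = ACS.standard((5, -1, 2))
        xf = align_acs(a, b)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, [5, -1, 2])

    def test_align_rotated_copy_reproduces_axes(self):
        a = ACS.standard()
        m = elementary_euler_product(30, 20, -40)
        b = ACS.from_matrix((0, 0, 0), m)
        xf = align_acs(a, b)
        moved = a.transformed(xf)
        np.testing.assert_allclose(moved.matrix, b.matrix, atol=1e-9)
        np.testing.assert_allclose(moved.origin, b.origin, atol=1e-9)


class TestRotateAboutLar:
    def test_zero_unchanged(self):
        a = ACS.standard((1, 1, 1))
        out = rotate_acs_about_lar(a, 0.0)
        np.testing.assert_allclose(out.matrix, a.matrix, atol=1e-12)

    def test_quarter_turn(self):
        a = ACS.standard()
        out = rotate_acs_about_lar(a, 90.0)
        # right-hand rule about +X: y -> z, z -> -y
        np.testing.assert_allclose(out.z_axis, -a.y_axis, atol=1e-9)
        assert abs(out.z_axis @ a.z_axis) < 1e-9
        np.testing.assert_allclose(out.origin, a.origin)

    def test_full_turn_periodicity(self):
        a = ACS.from_matrix((0, 0, 0), elementary_euler_product(10, 20, 30))
        out = rotate_acs_about_lar(a, 360.0)
        np.testing.assert_allclose(out.matrix, a.matrix, atol=1e-9)


class TestJointBuilders:
    def test_hip_cartilage_offset_center(self):
        # femoral frame translated 10.83 mm laterally (+X) and 6.28 mm
        # dorsally (-Z) in acetabular coordinates; center at the midpoint
        acet = ACS.standard((2.0, 1.0, 0.0))
        joint = build_hip_joint(acet, ACS.standard((2.0, 1.0, 0.0)),
                                cartilage_offset=(10.83, 0.0, -6.28))
        offset_origin = acet.origin + np.array([10.83, 0.0, -6.28])
        np.testing.assert_allclose(
            joint.rotation_center(), (acet.origin + offset_origin) / 2
        )

    def test_hip_zero_offset_center_at_shared_origin(self):
        acet = ACS.standard((3, 3, 3))
        joint = build_hip_joint(acet, ACS.standard((3, 3, 3)))
        np.testing.assert_allclose(joint.rotation_center(), [3, 3, 3])

    def test_hip_midpoint_arithmetic(self):
        joint = build_hip_joint(
            ACS.standard(), ACS.standard(), cartilage_offset=(8.0, 0, 0)
        )
        np.testing.assert_allclose(joint.rotation_center(), [4.0, 0, 0])

    @pytest.mark.parametrize("spacing", [20.0, 29.0, 35.9])
    def test_knee_spacing_presets(self, spacing):
        """Options A (20 mm), B (29 mm), C (35.9 mm): the null-pose distance
        between the femoral and crus ACSs along local X equals the spacing."""
        femoral = ACS.standard((0, 0, 0))
        crus = ACS.standard((0, 0, 0))
        joint = build_hinge_knee(femoral, crus, spacing_mm=spacing)
        xf = joint_child_transform(joint, EulerPose())
        crus_origin = xf.apply(crus.origin)
        sep = (crus_origin - femoral.origin) @ femoral.x_axis
        assert sep == pytest.approx(spacing)

    def test_knee_spacing_rotation_independent(self):
        joint = build_hinge_knee(ACS.standard(), ACS.standard(), 29.0)
        for fe in (45.0, 0.0):
            _ = joint_child_transform(joint, EulerPose(fe, 0, 0))
        # fixed translation offset: returning to null restores separation
        xf = joint_child_transform(joint, EulerPose())
        sep = xf.apply(np.zeros(3))[0]
        assert sep == pytest.approx(29.0, abs=1e-6)

    def test_knee_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_hinge_knee(ACS.standard(), ACS.standard(), 0.0)

    @pytest.mark.parametrize(
        "tibia,fraction,expected",
        [(100.0, 0.26, 26.0), (250.0, 0.26, 65.0)],
    )
    def test_relative_spacing_rule(self, tibia, fraction, expected):
        assert relative_spacing_from_reference(tibia, fraction) == pytest.approx(
            expected
        )

    def test_relative_spacing_zero_fraction_flows_downstream(self):
        spacing = relative_spacing_from_reference(100.0, 0.0)
        assert spacing == 0.0
        with pytest.raises(ValueError):
            build_hinge_knee(ACS.standard(), ACS.standard(), spacing)


def _two_joint_rig() -> KinematicRig:
    mesh = make_box((1, 1, 1))
    acet = ACS.standard((5.0, 0.0, 0.0))
    head = ACS.standard((0.0, 0.0, 0.0))
    distal_fem = ACS.from_matrix(
        (40.0, 0.0, 0.0), elementary_euler_product(0, 0, 15)
    )
    crus_prox = ACS.standard((0.0, 0.0, 0.0))
    hip = build_hip_joint(acet, head, cartilage_offset=(2.0, 0.0, -1.0))
    knee = build_hinge_knee(distal_fem, crus_prox, spacing_mm=3.0)
    bones = {
        "pelvis": Bone("pelvis", mesh, {"acetabular": acet}),
        "femur": Bone("femur", mesh, {}),
        "tibia": Bone("tibia", mesh, {}),
        "fibula": Bone("fibula", mesh, {}),
    }
    joints = [
        Joint(hip, "pelvis", ("femur",)),
        Joint(knee, "femur", ("tibia", "fibula")),
    ]
    return KinematicRig(bones, joints, "pelvis")


class TestForwardKinematics:
    def test_null_pose_knee_extended(self):
        rig = _two_joint_rig()
        world = forward_kinematics(rig, {})
        knee = rig.joint("knee").definition
        crus_acs_world = knee.distal_acs.transformed(world["tibia"])
        femoral_acs_world = knee.proximal_acs.transformed(world["femur"])
        np.testing.assert_allclose(
            crus_acs_world.matrix, femoral_acs_world.matrix, atol=1e-9
        )

    def test_hip_flexion_oracle(self):
        rig = _two_joint_rig()
        world = forward_kinematics(rig, {"hip": EulerPose(45, 0, 0)})
        hip = rig.joint("hip").definition
        ap = hip.proximal_acs.matrix
        want = ap @ elementary_euler_product(45, 0, 0) @ ap.T
        # femur world rotation = hip-frame-conjugated Euler rotation
        np.testing.assert_allclose(world["femur"].rotation, want, atol=1e-9)

    def test_two_joint_brute_composition(self):
        rig = _two_joint_rig()
        hip_pose = EulerPose(33.0, -21.0, 64.0)
        knee_pose = EulerPose(-47.0, 12.0, -8.0)
        world = forward_kinematics(rig, {"hip": hip_pose, "knee": knee_pose})

        def brute(joint: JointDefinition, pose, point):
            ap, op = joint.proximal_acs.matrix, joint.proximal_acs.origin
            ad, od = joint.distal_acs.matrix, joint.distal_acs.origin
            t, off = joint.center_fraction, joint.spacing_offset
            re = elementary_euler_product(
                pose.fe_deg, pose.abad_deg, pose.lar_deg
            )
            return op + ap @ (t * off + re @ ((1 - t) * off + ad.T @ (point - od)))

        rng = np.random.default_rng(7)
        for point in rng.uniform(-20, 20, size=(5, 3)):
            via_femur = brute(rig.joint("knee").definition, knee_pose, point)
            want = brute(rig.joint("hip").definition, hip_pose, via_femur)
            np.testing.assert_allclose(
                world["tibia"].apply(point), want, atol=1e-9
            )

    @given(
        fe=angle, ab=abad_angle, la=angle, kfe=angle, kab=abad_angle, kla=angle
    )
    @settings(max_examples=30, deadline=None)
    def test_transforms_always_orthonormal(self, fe, ab, la, kfe, kab, kla):
        rig = _two_joint_rig()
        world = forward_kinematics(
            rig,
            {"hip": EulerPose(fe, ab, la), "knee": EulerPose(kfe, kab, kla)},
        )
        for xf in world.values():
            r = xf.rotation
            np.testing.assert_allclose(r.T @ r, np.eye(3), atol=1e-9)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_joint_order_irrelevant_and_deterministic(self):
        rig = _two_joint_rig()
        c1 = {"hip": EulerPose(10, 5, -20), "knee": EulerPose(30, 0, 0)}
        c2 = {"knee": EulerPose(30, 0, 0), "hip": EulerPose(10, 5, -20)}
        w1 = forward_kinematics(rig, c1)
        w2 = forward_kinematics(rig, c2)
        for b in w1:
            np.testing.assert_array_equal(w1[b].rotation, w2[b].rotation)
            np.testing.assert_array_equal(w1[b].translation, w2[b].translation)

    def test_distal_joint_leaves_ancestors_fixed(self):
        rig = _two_joint_rig()
        base = forward_kinematics(rig, {"hip": EulerPose(15, -5, 40)})
        moved = forward_kinematics(
            rig, {"hip": EulerPose(15, -5, 40), "knee": EulerPose(80, 10, -30)}
        )
        for bone in ("pelvis", "femur"):
            np.testing.assert_array_equal(
                base[bone].rotation, moved[bone].rotation
            )
            np.testing.assert_array_equal(
                base[bone].translation, moved[bone].translation
            )

    def test_pose_outside_joint_limits_rejected(self):
        rig = _two_joint_rig()
        limited = JointDefinition(
            name="hip",
            proximal_acs=rig.joint("hip").definition.proximal_acs,
            distal_acs=rig.joint("hip").definition.distal_acs,
            limits={"fe": (-30.0, 30.0), "abad": (-90.0, 90.0),
                    "lar": (-180.0, 180.0)},
        )
        with pytest.raises(PoseLimitError, match="fe"):
            joint_child_transform(limited, EulerPose(45, 0, 0))
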