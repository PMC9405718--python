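"""Grid enumeration, collision sweeps, Table-style summaries, CSV I/O."""
import numpy as np
import pytest

from osteorom.errors import GridError
from osteorom.geometry import RigidTransform, transform_mesh, meshes_intersect
from osteorom.kinematics import ACS, EulerPose, JointDefinition, \
    euler_to_matrix, joint_child_transform
from osteorom.primitives import make_box
from osteorom.rom_sampler import (
    ViabilityGrid,
    generate_grid,
    read_viability_csv,
    sample_rom,
    summarize_rom,
    write_viability_csv,
)


class TestGenerateGrid:
    def test_standard_five_degree_grid_count(self):
        grid = generate_grid(5.0)
        assert grid.n_poses == 186_624  # 72 * 36 * 72 unique poses

    def test_coarse_grid_count(self):
        grid = generate_grid(90.0)
        assert grid.n_poses == 32  # 4 * 2 * 4

    def test_indivisible_step_rejected(self):
        with pytest.raises(GridError, match="divide"):
            generate_grid(7.0)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(GridError):
            generate_grid(0.0)

    def test_half_open_endpoints(self):
        grid = generate_grid(5.0)
        assert grid.fe_values[0] == -180.0 and grid.fe_values[-1] == 175.0
        assert grid.abad_values[0] == -90.0 and grid.abad_values[-1] == 85.0

    def test_ordering_fe_outer_lar_inner(self):
        poses = generate_grid(90.0).poses()
        assert tuple(poses[0]) == (-180.0, -90.0, -180.0)
        assert tuple(poses[1]) == (-180.0, -90.0, -90.0)  # LAR varies fastest
        assert poses[-1][0] == 90.0


def _separated_joint():
    """Joint whose meshes can never touch at any rotation."""
    prox = make_box((1.0, 1.0, 1.0), center=(-30.0, 0.0, 0.0))
    dist = make_box((1.0, 1.0, 1.0), center=(3.0, 0.0, 0.0))
    joint = JointDefinition(
        name="free", proximal_acs=ACS.standard(), distal_acs=ACS.standard(),
        rotation_center_mode="at_proximal",
    )
    return joint, prox, dist


class TestSampleRom:
    def test_never_touching_meshes_all_viable(self):
        joint, prox, dist = _separated_joint()
        vg = sample_rom(joint, prox, dist, generate_grid(45.0))
        assert vg.viable.all()

    def test_socket_cone_extremes_within_one_step(self, socket_fixture,
                                                  socket_vg15):
        _, _, _, pred = socket_fixture
        summary = summarize_rom(socket_vg15)
        step = socket_vg15.grid.step_deg
        for axis in ("fe", "abad"):
            assert abs(summary.value(axis, "max") - pred.threshold_deg) < step
            assert abs(summary.value(axis, "min") + pred.threshold_deg) < step

    def test_matches_per_pose_intersection_loop(self, socket_fixture):
        """Viable count equals an independent loop calling meshes_intersect
        with explicitly composed per-pose transforms."""
        cup, neck, joint, _ = socket_fixture
        grid = generate_grid(30.0)
        vg = sample_rom(joint, cup, neck, grid)
        ident = RigidTransform()
        brute = []
        for pose in grid.poses():
            xf = joint_child_transform(joint, EulerPose(*pose))
            brute.append(not meshes_intersect(neck, xf, cup, ident))
        brute = np.array(brute)
        assert (vg.viable == brute).all()

    def test_refinement_preserves_coarse_verdicts(self, socket_fixture):
        cup, neck, joint, _ = socket_fixture
        coarse = sample_rom(joint, cup, neck, generate_grid(60.0))
        fine = sample_rom(joint, cup, neck, generate_grid(30.0))
        fine_lookup = {
            tuple(p): v
            for p, v in zip(fine.grid.poses(), fine.viable)
        }
        for pose, flag in zip(coarse.grid.poses(), coarse.viable):
            assert fine_lookup[tuple(pose)] == flag

    def test_non_watertight_mesh_named_in_error(self):
        joint, prox, dist = _separated_joint()
        from osteorom.geometry import TriMesh

        broken = TriMesh(dist.vertices, dist.faces[:-1], name="distal_bad")
        with pytest.raises(Exception, match="distal_bad"):
            sample_rom(joint, prox, broken, generate_grid(90.0))


class TestSummarize:
    def test_fully_viable_standard_grid_endpoints(self):
        grid = generate_grid(5.0)
        vg = ViabilityGrid(grid, np.ones(grid.n_poses, dtype=bool))
        s = summarize_rom(vg)
        assert s.value("fe", "max") == 175.0
        assert s.value("fe", "min") == -180.0
        assert s.value("abad", "max") == 85.0
        assert s.value("lar", "max") == 175.0
        # extrema reported with minimal-companion tie-break: zeros
        assert s.extrema[("fe", "max")] == (175.0, 0.0, 0.0)

    def test_single_viable_pose_reported_everywhere(self):
        grid = generate_grid(5.0)
        flags = np.zeros(grid.n_poses, dtype=bool)
        poses = grid.poses()
        target = np.array([10.0, -5.0, 20.0])
        idx = np.nonzero((poses == target).all(axis=1))[0][0]
        flags[idx] = True
        s = summarize_rom(ViabilityGrid(grid, flags))
        for key, triple in s.extrema.items():
            assert triple == (10.0, -5.0, 20.0)

    def test_tie_break_minimal_companions_then_lexicographic(self):
        grid = generate_grid(45.0)
        poses = grid.poses()
        flags = np.zeros(grid.n_poses, dtype=bool)
        # two poses achieve max FE = 135: (135, 45, 0) and (135, 0, 45);
        # equal companion sums, lexicographic order prefers (135, 0, 45)
        for target in ([135.0, 45.0, 0.0], [135.0, 0.0, 45.0], [0.0, 0.0, 0.0]):
            idx = np.nonzero((poses == np.array(target)).all(axis=1))[0][0]
            flags[idx] = True
        s = summarize_rom(ViabilityGrid(grid, flags))
        assert s.extrema[("fe", "max")] == (135.0, 0.0, 45.0)

    def test_empty_viable_set_rejected(self):
        grid = generate_grid(90.0)
        vg = ViabilityGrid(grid, np.zeros(grid.n_poses, dtype=bool))
        with pytest.raises(GridError, match="no viable"):
            summarize_rom(vg)

    def test_hinge_band_edges_near_analytic_stops(self, hinge_fixture,
                                                  hinge_vg15):
        """The contiguous viable band around the null pose ends within one
        grid step of each closed-form clearance/trough stop.  (Full-axis
        extrema are not used for LAR: the rectangular bar is symmetric under
        a half-turn, so LAR near +/-180 is legitimately viable again.)"""
        _, _, _, pred = hinge_fixture
        step = hinge_vg15.grid.step_deg
        lookup = {
            tuple(p): v
            for p, v in zip(hinge_vg15.grid.poses(), hinge_vg15.viable)
        }

        def band_edge(axis):
            idx = {"fe": 0, "abad": 1, "lar": 2}[axis]
            last = 0.0
            val = 0.0
            while True:
                val += step
                pose = [0.0, 0.0, 0.0]
                pose[idx] = val
                if tuple(pose) not in lookup or not lookup[tuple(pose)]:
                    return last
                last = val

        assert abs(band_edge("fe") - pred.fe_stop_deg()) < step
        assert abs(band_edge("abad") - pred.abad_threshold_deg()) < step
        assert abs(band_edge("lar") - pred.lar_threshold_deg()) < step


class TestViabilityCsv:
    def test_round_trip_identical(self, tmp_path, socket_fixture):
        cup, neck, joint, _ = socket_fixture
        vg = sample_rom(joint, cup, neck, generate_grid(45.0))
        path = tmp_path / "v.csv"
        write_viability_csv(vg, path)
        back = read_viability_csv(path)
        assert (back.viable == vg.viable).all()
        assert back.grid == vg.grid
        assert back.joint_name == vg.joint_name
        assert back.provenance["proximal_mesh"] == "socket_cup"

    def test_row_count_matches_grid(self, tmp_path):
        grid = generate_grid(90.0)
        vg = ViabilityGrid(grid, np.ones(32, dtype=bool), joint_name="j")
        path = write_viability_csv(vg, tmp_path / "v.csv")
        lines = path.read_text().splitlines()
        data = [ln for ln in lines if not ln.startswith("#")]
        assert len(data) == 32 + 1  # header + one row per pose

    def test_header_grid_mismatch_detected(self, tmp_path):
        grid = generate_grid(90.0)
        vg = ViabilityGrid(grid, np.ones(32, dtype=bool))
        path = write_viability_csv(vg, tmp_path / "v.csv")
        text = path.read_text().replace("step_deg=90", "step_deg=45")
        path.write_text(text)
        with pytest.raises(GridError):
            read_viability_csv(path)
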