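import numpy as np
import pytest

from osteorom import fixtures as fx
from osteorom import rom_sampler as rs


@pytest.fixture(scope="session")
def socket_fixture():
    """Default socket joint: (cup, neck, joint, predicate)."""
    return fx.make_socket_joint()


@pytest.fixture(scope="session")
def hinge_fixture():
    return fx.make_hinge_joint()


@pytest.fixture(scope="session")
def socket_vg15(socket_fixture):
    """15-degree viability grid of the default socket joint."""
    cup, neck, joint, _ = socket_fixture
    return rs.sample_rom(joint, cup, neck, rs.generate_grid(15.0))


@pytest.fixture(scope="session")
def hinge_vg15(hinge_fixture):
    trough, bar, joint, _ = hinge_fixture
    return rs.sample_rom(joint, trough, bar, rs.generate_grid(15.0))


@pytest.fixture(scope="session")
def hinge_vg5(hinge_fixture):
    """5-degree hinge grid: needed wherever a 3D viable cloud is required
    (the 15-degree hinge viable set is coplanar at ABAD = 0, since the
    clearance threshold ~8.2 deg is below the step)."""
    trough, bar, joint, _ = hinge_fixture
    return rs.sample_rom(joint, trough, bar, rs.generate_grid(5.0))


@pytest.fixture(scope="session")
def socket_shape15(socket_vg15):
    """Auto-radius alpha shape over the 15-degree socket viable poses."""
    from osteorom import pose_space as ps

    pts = socket_vg15.viable_poses()
    r = ps.auto_radius(pts)
    return ps.build_alpha_shape(pts, r)


@pytest.fixture(scope="session")
def hinge_shape5(hinge_vg5):
    from osteorom import pose_space as ps

    pts = hinge_vg5.viable_poses()
    r = ps.auto_radius(pts)
    return ps.build_alpha_shape(pts, r)


def random_blob_mesh(rng, kind=None):
    """Random low-poly watertight mesh (sphere or box), randomly posed."""
    from osteorom.geometry import RigidTransform, transform_mesh
    from osteorom.primitives import make_box, make_uv_sphere
    from scipy.spatial.transform import Rotation

    kind = kind or rng.choice(["sphere", "box"])
    if kind == "sphere":
        mesh = make_uv_sphere(
            rng.uniform(0.5, 2.0), n_azimuth=10, n_polar=6
        )
    else:
        mesh = make_box(rng.uniform(0.3, 1.5, size=3))
    rot = Rotation.random(rng=rng).as_matrix()
    xf = RigidTransform(rot, rng.uniform(-1.5, 1.5, size=3))
    return transform_mesh(mesh, xf)
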