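import numpy as np
import pytest
import trimesh

from hipsim import CamSpec, PhantomSpec, generate_phantom
from hipsim.mesh_core import TriangleMesh


def make_sphere(radius=1.0, center=(0.0, 0.0, 0.0), subdivisions=3, name="sphere"):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    m.apply_translation(center)
    return TriangleMesh(m.vertices, m.faces, name)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from hipsim.mesh_core import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return RigidTransform(R.as_matrix(), rng.normal(scale=20.0, size=3))


@pytest.fixture(scope="session")
def cam_phantom_small():
    """Default-geometry cam phantom at reduced tessellation (fast sweeps)."""
    return generate_phantom(PhantomSpec(cam=CamSpec()), mesh_resolution=3)


@pytest.fixture(scope="session")
def native_phantom_small():
    return generate_phantom(PhantomSpec(), mesh_resolution=3)


@pytest.fixture(scope="session")
def cam_phantom_default():
    """Full-resolution default cam phantom (oracle-grade accuracy)."""
    return generate_phantom(PhantomSpec(cam=CamSpec()), mesh_resolution=4)
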