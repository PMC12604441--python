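import numpy as np
import pytest
import trimesh

import kneeshape as ks


@pytest.fixture(scope="session")
def patella():
    return ks.patella_template()


@pytest.fixture(scope="session")
def small_template():
    """Coarse template (42 points) used for recovery experiments."""
    return ks.patella_template(subdivisions=1)


@pytest.fixture(scope="session")
def bumpy_shape():
    """A chiral, rotationally asymmetric closed surface for registration
    tests (an ellipsoid with seeded smooth bumps)."""
    base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    v = base.vertices * np.array([15.0, 17.5, 7.5])
    rng = np.random.default_rng(42)
    centers = v[rng.choice(len(v), 6, replace=False)]
    for c in centers:
        d2 = ((v - c) ** 2).sum(axis=1)
        v = v + np.outer(np.exp(-d2 / 50.0), c / np.linalg.norm(c)) * 3.0
    return trimesh.Trimesh(v, base.faces, process=False)


@pytest.fixture(scope="session")
def sphere_volume():
    """Voxelized r=10 mm sphere at the scanner's 0.7 mm isotropic spacing."""
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return ks.voxelize(sphere, spacing=0.7)


def rotation_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0.0],
                     [np.sin(a), np.cos(a), 0.0],
                     [0.0, 0.0, 1.0]])
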