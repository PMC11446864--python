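import numpy as np
import pytest

import vrakit as vk


@pytest.fixture(scope="session")
def small_bone():
    """A reduced long bone (120 mm) used across the suite for speed."""
    return vk.make_long_bone(
        length=120.0, shaft_radius=10.0, end_radius=16.0, seed=7, n_axial=90, n_theta=64
    )


@pytest.fixture(scope="session")
def fractured_small_bone(small_bone):
    """Five fragments of the small bone, with ground truth."""
    fragments, truth = vk.fracture(small_bone, 5, seed=11, n_surface_points=9000)
    return fragments, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """A uniformly random proper rigid transform (helper, not a fixture)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return vk.RigidTransform(rot, rng.uniform(-50, 50, 3))
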