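import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pcsloc import ChiTensor


def random_tensor(rng, max_offset=10.0):
    """Generic traceless tensor with a random metal position."""
    comps = rng.uniform(-20.0, 20.0, size=5)
    position = rng.uniform(-max_offset, max_offset, size=3)
    return ChiTensor(position=position, comps=comps)


def random_point_near(rng, center, rmin=2.0, rmax=30.0):
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return np.asarray(center) + u * rng.uniform(rmin, rmax)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def axial_tensor():
    """Axial tensor at the origin: eigenvalues (−1, −1, 2), z along lab z."""
    return ChiTensor(position=[0.0, 0.0, 0.0], comps=[-1.0, -1.0, 0.0, 0.0, 0.0])


@pytest.fixture
def random_rotation(rng):
    return Rotation.random(rng=rng)
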