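import numpy as np
import pytest

from hodgeimage import GridSpec, normal_support, tangential_support
from hodgeimage.fixtures import FixtureSpec, make_mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_mask(shape, rng, p=0.5):
    """Random boolean mask, rejection-sampled to be nonempty."""
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


@pytest.fixture(scope="session")
def annulus_mask():
    return make_mask(FixtureSpec("annulus", (32, 32)))[0]


@pytest.fixture(scope="session")
def disk_mask():
    return make_mask(FixtureSpec("disk", (24, 24)))[0]


@pytest.fixture(scope="session")
def annulus_support(annulus_mask):
    return normal_support(GridSpec(annulus_mask.shape), annulus_mask)


@pytest.fixture(scope="session")
def disk_support(disk_mask):
    return normal_support(GridSpec(disk_mask.shape), disk_mask)
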