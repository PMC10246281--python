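import numpy as np
import pytest
from hypothesis import settings

import radtract as rt

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tube_bundle():
    """Small straight-tube phantom shared across tests."""
    spec = rt.PhantomSpec(
        shape="tube",
        length=40.0,
        radius=3.0,
        n_streamlines=100,
        jitter=0.2,
        grid_shape=(24, 24, 50),
        seed=11,
    )
    return rt.make_bundle(spec)


@pytest.fixture(scope="session")
def fan_bundle():
    spec = rt.PhantomSpec(
        shape="fan",
        length=48.0,
        radius=3.0,
        fan_angle=60.0,
        n_streamlines=150,
        jitter=0.2,
        grid_shape=(90, 90, 70),
        seed=13,
    )
    return rt.make_bundle(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def identity_image():
    return rt.ScalarImage(np.zeros((10, 10, 10)), np.eye(4))
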