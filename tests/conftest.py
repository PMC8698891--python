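import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vitreoct as vo

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_calibration():
    return vo.default_calibration()


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless default-geometry scene at a reduced lateral width."""
    return vo.make_scene((496, 512), speckle_shape=None)


@pytest.fixture(scope="session")
def clean_calibration():
    return vo.default_calibration(512, 496)


@pytest.fixture(scope="session")
def speckle_scene():
    return vo.make_scene((248, 512), speckle_shape=10.0)


@pytest.fixture(scope="session")
def speckle_calibration():
    return vo.default_calibration(512, 248)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
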