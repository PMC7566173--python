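import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import linefollow as lf

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_course():
    """All-vertical course: the line never moves sideways."""
    return lf.Course.from_angles([90] * 25, start_x=150.0, x_bounds=(0.0, 300.0))


@pytest.fixture
def zigzag_course():
    """Alternating 45/135 course (a corner at every junction)."""
    return lf.Course.from_angles([45, 135] * 13, start_x=150.0, x_bounds=(0.0, 300.0))


@pytest.fixture
def short_config():
    """A 2 s trial configuration for fast engine-level tests."""
    return lf.EnvConfig(ca=0.6, cm=0.6, trial_duration=2.0)
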