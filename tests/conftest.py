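import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishtrack3d.synthgen import SimConfig, TankGeometry

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_small_config(**overrides) -> SimConfig:
    """A fast render geometry: 700x560 frames, same 1 mm/px calibration."""
    kwargs = dict(
        duration_s=30.0,
        frame_width=700,
        frame_height=560,
        roi_front=(80, 80, 620, 480),
        roi_top=(80, 95, 620, 465),
        seed=0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture
def small_config():
    return make_small_config()


@pytest.fixture
def tank():
    return TankGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
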