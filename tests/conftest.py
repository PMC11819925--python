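import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import run2d as r
from run2d.simulate import hip_params

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model25():
    return r.default_model(2.5)


@pytest.fixture(scope="session")
def model36():
    return r.default_model(3.6)


@pytest.fixture(scope="session")
def calib25(model25):
    return r.static_calibration(r.render_static(model25))


@pytest.fixture(scope="session")
def clean_trial25(model25):
    """Noise-free 30 s trial at 2.5 m/s with a butt-kick at 1 s."""
    return r.render_streams(model25, r.NoiseSpec(seed=1), 30.0, trigger_at_s=1.0)


@pytest.fixture(scope="session")
def noisy_trial25(model25):
    """2 px pixel noise, 2% dropouts, butt-kick at 1 s."""
    noise = r.NoiseSpec(pixel_noise_sd=2.0, gap_probability=0.02, seed=1)
    return r.render_streams(model25, noise, 30.0, trigger_at_s=1.0)


@pytest.fixture(scope="session")
def hip_params25(model25):
    return hip_params(model25)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
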