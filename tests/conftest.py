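import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vasoreact import FmdSimParams, generate_fmd_trace

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_trace():
    """Noiseless FMD recording: baseline 0.30 cm, 10% dilation peaking at 30 s."""
    return generate_fmd_trace(FmdSimParams(
        baseline_diameter=0.30, fmd_percent=10.0, time_to_peak=30.0,
        noise_sd_diameter=0.0, noise_sd_velocity=0.0, seed=0,
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
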