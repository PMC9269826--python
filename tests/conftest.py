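import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rppgvitals as rv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_store():
    """A 60-s, 30-fps recording at HR 72 / SpO2 96 with mild noise."""
    cfg = rv.SimulationConfig(seed=11)
    truth = rv.generate_ground_truth(cfg)
    return rv.generate_region_store(truth, cfg), truth, cfg


@pytest.fixture(scope="session")
def noiseless_store():
    cfg = rv.SimulationConfig(seed=12, noise_sd=0.0, jitter_ms=0.0)
    truth = rv.generate_ground_truth(cfg)
    return rv.generate_region_store(truth, cfg), truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
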