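import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import porekinetics as pk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cfg() -> pk.SimulationConfig:
    """Noiseless, unfiltered recording with all three event classes."""
    return pk.SimulationConfig(
        duration_s=30.0,
        species=pk.condition_species("cc_ag", duplex_rate_hz=0.4, ss_rate_hz=1.0),
        noise_sd_pa=0.0,
        filter_cutoff_hz=None,
        seed=5,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_cfg):
    truth = pk.sample_event_train(noiseless_cfg)
    trace = pk.render_trace(truth, noiseless_cfg)
    return truth, trace


@pytest.fixture(scope="session")
def noisy_recording():
    """Default study conditions: 2 pA noise, 5 kHz filter, mixed classes."""
    cfg = pk.SimulationConfig(
        duration_s=60.0,
        species=pk.condition_species("cc_ag", duplex_rate_hz=0.4),
        seed=11,
    )
    truth = pk.sample_event_train(cfg)
    trace = pk.render_trace(truth, cfg)
    return cfg, truth, trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
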