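import numpy as np
import pytest

from phrenic import DrugProtocol, SynthConfig, simulate_subject


@pytest.fixture
def fast_protocol():
    """Short single-injection protocol used by most session-level tests."""
    return DrugProtocol("BotC", "vehicle", [150.0], pre_duration=150.0,
                        post_duration=100.0)


@pytest.fixture
def noiseless_session(fast_protocol):
    """Deterministic session: envelope carrier, no cycle variability."""
    cfg = SynthConfig(Ti0=0.9, Te0=3.1, cv_cycle=0.0, noise_floor=0.0,
                      carrier_mode="envelope", seed=3)
    return simulate_subject(cfg, fast_protocol)


@pytest.fixture
def noisy_session(fast_protocol):
    """Session at the default multiunit noise level."""
    return simulate_subject(SynthConfig(seed=11), fast_protocol)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
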