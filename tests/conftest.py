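import numpy as np
import pytest
from hypothesis import settings

import fluorlock as fl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> fl.DemodConfig:
    """Default demodulator configuration (200 kHz, m=488, two stages)."""
    return fl.DemodConfig()


@pytest.fixture(scope="session")
def clean_frontend() -> fl.FrontEndModel:
    """Front end with every stochastic or distorting term switched off."""
    return fl.FrontEndModel(
        white_sd=0.0, mains_amp=0.0, ambient_dc=0.0, led_tau_on=0.0
    )


@pytest.fixture(scope="session")
def settled_unit_tone(cfg):
    """A unit-amplitude tone at f0, long enough to be fully settled (12 tau)."""
    n = np.arange(fl.settling_samples(cfg, 12))
    return np.cos(2 * np.pi * n / cfg.m)
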