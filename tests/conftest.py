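"""Shared fixtures: small seeded synthetic sessions, reused across tests."""

import numpy as np
import pytest

from eegbattery import synth
from eegbattery.core import extract_epochs
from eegbattery.synth import AssrParams, BackgroundParams, ErpKernelParams


@pytest.fixture(scope="session")
def gating_session():
    """100-trial paired-tone session, g = 0.25, moderate noise."""
    kernel = ErpKernelParams(gating_factor=0.25)
    noise = BackgroundParams(rms=30.0)
    return synth.simulate_gating_session(100, kernel, noise, seed=12345)


@pytest.fixture(scope="session")
def gating_epochs(gating_session):
    rec, events, _ = gating_session
    return extract_epochs(rec, events, "tone_S1", (1.0, 4.0), "frontal")


@pytest.fixture(scope="session")
def social_session():
    """40 investigations, programmed elicited ratio 150 %, no coupling."""
    bursts = synth.GammaBurstParams(elicited_ratio=150.0, coupling=0.0)
    return synth.simulate_social_session(40, bursts, seed=77)


@pytest.fixture(scope="session")
def assr_session_locked():
    """100 trains, zero phase jitter."""
    return synth.simulate_assr_session(100, AssrParams(phase_jitter_sd=0.0), seed=5)


@pytest.fixture(scope="session")
def sleep_session():
    """40 min sleep session at the default 6/min spindle density."""
    return synth.simulate_sleep_session(duration=2400.0, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
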