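"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest

from rsvpauth import SimConfig, experiments, simulate

SEED = 7


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_config():
    """4-block session: 40 trials, enough for smoke-level classification."""
    return SimConfig(n_blocks=4, seed=SEED)


@pytest.fixture(scope="session")
def quiet_config():
    """Low-noise 4-block session for high-SNR end-to-end checks."""
    return SimConfig(n_blocks=4, noise_rms=3.0, common_noise_rms=1.0, seed=SEED)


@pytest.fixture(scope="session")
def quiet_epochs(quiet_config):
    """Classification-ready user+imposter epochs, strongly separable."""
    return experiments.session_epochs(quiet_config, include=("user", "blind"))


@pytest.fixture(scope="session")
def medium_epochs():
    """Default-noise 10-block user+both-imposters dataset (150 paired trials)."""
    config = SimConfig(n_blocks=10, seed=SEED)
    return experiments.session_epochs(config)


@pytest.fixture(scope="session")
def tiny_recording(small_config):
    return simulate.generate_recording(small_config)
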