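"""Shared fixtures: small deterministic sessions and signal parameter sets."""

import numpy as np
import pytest

from thetanav import SignalParams, task


@pytest.fixture(scope="session")
def small_session():
    """A walked 30-trial session used across signal and pipeline tests."""
    session = task.generate_session(n_trials=30, n_blocks=2, seed=11)
    return task.simulate_agent(session, p_correct=0.8, seed=12)


@pytest.fixture(scope="session")
def fast_params():
    """Reduced-rate generator parameters for cheap end-to-end tests."""
    return SignalParams(sample_rate=300.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
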