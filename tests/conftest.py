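import numpy as np
import pytest

from pacwm.synthetic import SyntheticConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session shared by read-only tests."""
    session, truth = simulate_session(seed=11)
    return session, truth


@pytest.fixture(scope="session")
def small_session():
    """A lighter session (fewer trials) for the expensive pipeline tests."""
    cfg = SyntheticConfig(n_trials=60, load_split=(30, 30), seed=21)
    session, truth = simulate_session(cfg)
    return session, truth
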