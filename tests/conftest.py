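import numpy as np
import pytest

from stopbayes import ObserverParams, RaceParams, SessionDesign, simulate_session


@pytest.fixture(scope="session")
def default_design():
    return SessionDesign(n_trials=400)


@pytest.fixture(scope="session")
def default_params():
    return RaceParams()


@pytest.fixture(scope="session")
def session_trials(default_design, default_params):
    """One 400-trial staircase-tracked session, fixed seed."""
    return simulate_session(default_design, default_params, seed=12345)


@pytest.fixture(scope="session")
def subject_sessions(default_params):
    """A study-protocol subject: four 100-trial sessions."""
    design = SessionDesign(n_trials=100)
    return [simulate_session(design, default_params, seed=900 + j) for j in range(4)]


@pytest.fixture(scope="session")
def observer_defaults():
    return ObserverParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
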