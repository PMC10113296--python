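import numpy as np
import pytest

from scopeskill.exercise import make_setup


@pytest.fixture(scope="session")
def setup():
    """Default exercise setup (geometry, camera, cavity, solved ideal poses)."""
    return make_setup()


@pytest.fixture(scope="session")
def mini_cohort(setup):
    """Small simulated cohort shared by agent/metric trend tests."""
    from scopeskill.agents import simulate_cohort
    from scopeskill.metrics import metrics_table

    sessions = simulate_cohort(8, setup, seed=11, n_trials=30)
    df = metrics_table(sessions, setup)
    return sessions, df


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
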