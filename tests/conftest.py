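import numpy as np
import pytest

import epibehave as eb


@pytest.fixture(scope="session")
def dparams():
    """Baseline disease parameters (R0 = 2.4 calibration)."""
    return eb.DiseaseParams()


@pytest.fixture(scope="session")
def bparams():
    return eb.BehaviorParams()


@pytest.fixture(scope="session")
def run_p33():
    """Adaptive run: one third risk-takers, 30% risk reduction for evaders."""
    return eb.simulate_adaptive(eb.ScenarioConfig(p=0.33, epsilon=0.7))


@pytest.fixture(scope="session")
def run_p66():
    """Adaptive run: two thirds risk-takers."""
    return eb.simulate_adaptive(eb.ScenarioConfig(p=0.66, epsilon=0.7))


def random_environment(rng: np.random.Generator, group: int) -> eb.PerceivedEnvironment:
    """A random but valid perceived environment for policy-solver tests."""
    state = eb.EpidemicState.from_array(rng.dirichlet(np.ones(8)))
    contacts = eb.ContactProfile.from_array(rng.uniform(1.0, 24.0, size=8))
    return eb.PerceivedEnvironment(state, contacts, group)
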