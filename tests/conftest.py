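import numpy as np
import pytest

from comrs import (
    Scenario,
    default_params,
    no_deg_params,
    simulate,
    steady_state,
)


@pytest.fixture(scope="session")
def deg_params():
    return default_params()


@pytest.fixture(scope="session")
def nodeg_params():
    return no_deg_params()


@pytest.fixture(scope="session")
def basal_state(deg_params):
    return steady_state(deg_params)


@pytest.fixture(scope="session")
def induction_traj(deg_params, basal_state):
    """Reference 8.5-fold ComR overexpression run with the deg player."""
    sc = Scenario(kind="comR_overexpression", comR_fold=8.5)
    return simulate(sc, deg_params, horizon=600.0, dt=1.0, y0=basal_state)


@pytest.fixture(scope="session")
def nodeg_traj(nodeg_params):
    sc = Scenario(kind="comR_overexpression", comR_fold=8.5)
    return simulate(sc, nodeg_params, horizon=600.0, dt=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20220525)
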