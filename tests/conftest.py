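import numpy as np
import pytest
from hypothesis import settings

import cellecon as ce
from cellecon.simulate import solve_steady_state

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_params():
    return ce.default_parameters()


@pytest.fixture(scope="session")
def single_cell_model(default_params):
    return ce.CellModel(default_params)


@pytest.fixture(scope="session")
def single_cell_steady(single_cell_model):
    """Steady state of the default cell in the exponential regime."""
    res = solve_steady_state(single_cell_model)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def chemostat_model_01(default_params):
    return ce.CellModel(default_params,
                        ce.CultureMode(mode="chemostat", delta=0.1))


@pytest.fixture(scope="session")
def circuit_chemostat_01(default_params):
    """Two-reporter circuit host in a chemostat at 0.1 /h."""
    return ce.two_reporter_circuit(
        ce.CellModel(default_params, ce.CultureMode(mode="chemostat", delta=0.1)))


def random_states(model, n, seed=0, scale=None):
    """Random nonnegative state vectors spanning realistic magnitudes."""
    rng = np.random.default_rng(seed)
    if scale is None:
        scale = np.full(model.n_species, 1e4)
        scale[model.index("S")] = 1e10
        scale[model.index("M")] = 1e6
        scale[model.index("tu")] = 1e6
        scale[model.index("tc")] = 1e6
    return 10.0 ** (rng.uniform(-1, 1, (n, model.n_species))) * scale * \
        rng.uniform(0.0, 1.0, (n, model.n_species))
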