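import numpy as np
import pytest

from phytostress.simulate import ScenarioSpec, simulate_experiment, single_plant


@pytest.fixture(scope="session")
def one_plant_spec():
    """Small single-bottle scenario used by several suites (3 days, 80 s cadence)."""
    return ScenarioSpec(n_plants=1, duration_days=3.0, cadence_s=80.0,
                        roles={1: "seed+filter"}, seed=7)


@pytest.fixture(scope="session")
def one_plant_series(one_plant_spec):
    return single_plant(simulate_experiment(one_plant_spec), 1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
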