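import numpy as np
import pytest

from rmcov import ParameterTable, ScenarioConfig, load_table1, simulate_dataset


@pytest.fixture(scope="session")
def params() -> ParameterTable:
    return load_table1()


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A quick scenario for unit tests (not one of the headline conditions)."""
    return ScenarioConfig(
        truth_structure="het_cs",
        n_per_group=6,
        rho=0.6,
        hypothesis="alternative",
        n_reps=50,
        base_seed=424242,
    )


@pytest.fixture(scope="session")
def small_dataset(params, small_scenario):
    """One balanced replicate: 3 arms x 6 subjects x 5 weeks."""
    return simulate_dataset(params, small_scenario, 0)


@pytest.fixture(scope="session")
def null_dataset(params):
    """One replicate generated with no treatment effect."""
    sc = ScenarioConfig(
        truth_structure="het_cs",
        n_per_group=12,
        rho=0.3,
        hypothesis="null",
        n_reps=10,
        base_seed=77,
    )
    return simulate_dataset(params, sc, 0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
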