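import numpy as np
import pandas as pd
import pytest

from cadgrs import GrsRiskModel, SimConfig, default_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel33():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel33):
    """A modest simulated case-control cohort used across modules."""
    cfg = SimConfig(n_cases=300, n_controls=260, seed=7,
                    population_multiplier=20)
    return simulate_cohort(cfg, panel33)


@pytest.fixture(scope="session")
def fitted_results(panel33):
    """One full analysis fit shared by the pipeline-level tests."""
    cfg = SimConfig(n_cases=800, n_controls=700, seed=3,
                    population_multiplier=20)
    return GrsRiskModel.from_simulation(cfg, panel=panel33).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
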