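import numpy as np
import pandas as pd
import pytest

from immunage import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60/group, 150 features, strong planted signal; shared across tests."""
    cfg = SimulationConfig(
        n_per_group=60, n_features=150, n_shared_age=10, n_groupA_only=5,
        n_groupB_only=5, n_opposite=3, effect_rho=0.5, n_plasma=10,
        group_index_shift=0.8, aging_rate_multiplier=1.18, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere: every downstream contrast is null."""
    cfg = SimulationConfig(
        n_per_group=60, n_features=150, n_shared_age=0, n_groupA_only=0,
        n_groupB_only=0, n_opposite=0, effect_rho=0.5, n_plasma=0,
        group_index_shift=0.0, aging_rate_multiplier=1.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20211011)
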