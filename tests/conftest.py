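import numpy as np
import pytest

from hypoburden.synthetic import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20181108)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    tables, truth = simulate_cohort(SimConfig(n_stays=400, seed=42))
    return tables, truth
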