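import numpy as np
import pytest

from nsdt import SimulationParams, simulate_cohort
from nsdt.pipeline import cohort_to_frames


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def cohort(default_params):
    """One default synthetic cohort, shared across tests."""
    return simulate_cohort(default_params, seed=11)


@pytest.fixture(scope="session")
def cohort_frames(cohort):
    return cohort_to_frames(cohort)
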