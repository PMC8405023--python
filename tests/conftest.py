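import numpy as np
import pytest

from bimeter.conditions import make_condition_grid
from bimeter.raters import CohortConfig, generate_cohort, simulate_experiment
from bimeter.synthesis import assemble_stimulus, condition_seed

MASTER_SEED = 20260929


@pytest.fixture(scope="session")
def paper_grid():
    return make_condition_grid()


@pytest.fixture(scope="session")
def grid_stimuli(paper_grid):
    """All 50 study-grid stimuli rendered once per session."""
    return [
        assemble_stimulus(c, seed=condition_seed(MASTER_SEED, c)) for c in paper_grid
    ]


@pytest.fixture(scope="session")
def paper_cohort():
    cohort = generate_cohort(CohortConfig(), seed=MASTER_SEED)
    return cohort


@pytest.fixture(scope="session")
def paper_trials(paper_cohort):
    return simulate_experiment(paper_cohort, seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
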