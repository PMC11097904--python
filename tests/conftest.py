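import numpy as np
import pytest

import rotovis as rv
from rotovis import psychfit as pf

# One seed constant for every stochastic fixture/test in the suite.
SEED = 1234


@pytest.fixture(scope="session")
def exp1_cohort():
    """Moderate direction-task cohort with the default (biased) population,
    shared across test modules to amortize simulation cost."""
    return rv.generate_cohort("exp1", 12, seed=SEED, with_trajectories=False)


@pytest.fixture(scope="session")
def exp1_threshold_table(exp1_cohort):
    return pf.build_threshold_table(exp1_cohort.trials, exp1_cohort.traces)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
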