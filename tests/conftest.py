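import numpy as np
import pytest

from gh2000 import default_daegu_like_params, simulate_cohort, workflows


@pytest.fixture(scope="session")
def male_cohort():
    """A mid-sized simulated male cohort with the default injected age effect."""
    params = default_daegu_like_params(n=400, seed=11)
    table, truth = simulate_cohort(params)
    return table, truth


@pytest.fixture(scope="session")
def scored_male_frame(male_cohort):
    table, _ = male_cohort
    return workflows.score_frame(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20161028)
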