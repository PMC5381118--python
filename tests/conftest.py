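import numpy as np
import pytest

from oxydyn import RunConfig, default_schedule, run_study, stimulated_harmonics

#: Forest size / row thinning used for cohort-level tests.  1-Hz physiological
#: rows are strongly autocorrelated, so thinning training rows and using a
#: moderate tree count loses almost no accuracy while keeping runtimes short.
COHORT_TEST_CONFIG = {
    "seed": 0,
    "forest": {"n_trees": 20, "min_leaf": 20, "train_stride": 2},
}


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def harmonics(schedule):
    return stimulated_harmonics(schedule)


@pytest.fixture(scope="session")
def study_bundle():
    """Full 16-participant synthetic study under default noise (shared, ~35 s)."""
    return run_study(RunConfig.model_validate(COHORT_TEST_CONFIG))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
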