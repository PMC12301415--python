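import numpy as np
import pytest

import floodrisk as fr
from floodrisk.optimizer import OptimizerConfig

#: cohort realization seed used throughout the suite (chosen once, up front)
COHORT_SEED = 7
MISSING_SEED = 8


@pytest.fixture(scope="session")
def default_spec():
    return fr.build_default_spec()


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """Complete (no missingness) default cohort."""
    return fr.generate_cohort(default_spec, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_with_missing(default_spec, default_cohort):
    return fr.inject_missingness(default_cohort, default_spec, seed=MISSING_SEED)


@pytest.fixture(scope="session")
def automl_model(cohort_with_missing):
    """The desk-scale AutoML fit (population 20, 60 iterations), shared by
    the end-to-end and interpretation tests because it is the expensive step."""
    opt = OptimizerConfig(population_size=20, max_iterations=60, variant="ifla", seed=0)
    return fr.fit_automl(cohort_with_missing, opt=opt)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
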