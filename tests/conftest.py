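import numpy as np
import pytest

from brainlayers import RunConfig, generate_cohort, run_group_module_analysis

#: master seed for all fixture randomness
SEED = 2024


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-group planted cohort (N=20, f=5, 15/group)."""
    return generate_cohort(seed=SEED)


@pytest.fixture(scope="session")
def default_report(default_cohort):
    """Full pipeline run on the default cohort (shared: it is the slow part)."""
    cfg = RunConfig(seed=SEED, run_nbs=False)
    return run_group_module_analysis(default_cohort, cfg)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return generate_cohort(seed=SEED, noise_sd=0.0)


@pytest.fixture(scope="session")
def zero_noise_report(zero_noise_cohort):
    cfg = RunConfig(seed=SEED, run_nbs=False, run_classifier=False, run_covariates=False)
    return run_group_module_analysis(zero_noise_cohort, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
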