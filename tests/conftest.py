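import numpy as np
import pytest
from hypothesis import settings

from gaitdfa import SimConfig, build_feature_matrix, generate_cohort

settings.register_profile("repro", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def cohort8():
    """8-subject cohort (2 singular) at default effect sizes."""
    return generate_cohort(SimConfig(n_subjects=8, n_singular_subjects=2, rng_seed=7))


@pytest.fixture(scope="session")
def features8(cohort8):
    return build_feature_matrix(cohort8)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects x (2+2) trials: the smallest cohort worth running end to end."""
    return generate_cohort(
        SimConfig(n_subjects=4, trials_per_condition=2, n_singular_subjects=0, rng_seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
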