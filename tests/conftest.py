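import pytest
from hypothesis import HealthCheck, settings

from cogdecline import (
    generate_cohort,
    label_cohort,
    study_like_config,
    published_model,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_config():
    """The stated-world generator configuration (seed fixed a priori)."""
    return study_like_config(seed=1)


@pytest.fixture(scope="session")
def big_cohort(study_config):
    """A large labeled cohort (n=20000) for recovery/convergence checks."""
    df = generate_cohort(study_config.replace(n_subjects=20000))
    return label_cohort(df)


@pytest.fixture(scope="session")
def four_question_model():
    return published_model()
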