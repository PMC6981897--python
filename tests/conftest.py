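import pytest

from hrmets import (
    CandidateSpec,
    DEFAULT_TRUTH,
    generate_observations,
    generate_subjects,
)


@pytest.fixture(scope="session")
def cohort():
    """Default 40-subject stratified cohort (20 male, 20 female)."""
    return generate_subjects(seed=7)


@pytest.fixture(scope="session")
def observations(cohort):
    """Pooled subject-activity observations, published-N missingness."""
    return generate_observations(cohort, truth=DEFAULT_TRUTH, seed=7)


@pytest.fixture(scope="session")
def spec_three_predictor():
    """The %HRR + resting HR + height candidate (the study's best model)."""
    return CandidateSpec(hr_variable="HRR", covariates=("height", "resting_hr"), family="A")


@pytest.fixture(scope="session")
def spec_single_predictor():
    """The %HRR-only candidate."""
    return CandidateSpec(hr_variable="HRR", covariates=(), family="A")
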