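import pytest

from crowdcal import SimulationConfig, load_quiz, simulate_cohort
from crowdcal.error_metrics import compute_metrics


@pytest.fixture(scope="session")
def quiz():
    return load_quiz("table1")


@pytest.fixture(scope="session")
def clean_cohort(quiz):
    """Unbiased moderate-noise cohort with no QC-removable records."""
    config = SimulationConfig(
        n_participants=120,
        n_experts=0,
        seed=42,
        sigma_noise=0.3,
        sd_food=0.0,
        p_invalid_bmi=0.0,
        p_missing_gender=0.0,
    )
    return simulate_cohort(quiz, config)


@pytest.fixture(scope="session")
def clean_metrics(quiz, clean_cohort):
    _, responses = clean_cohort
    return compute_metrics(responses, quiz)
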