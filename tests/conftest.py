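import pytest

from mammoscreen import aggregates, default_config, generate_cohort


@pytest.fixture(scope="session")
def study_exams():
    """Exam-level reconstruction of the full published study sample."""
    return aggregates.study_exams()


@pytest.fixture(scope="session")
def study_priors():
    return aggregates.study_prior_exams()


@pytest.fixture(scope="session")
def vdg4_exams():
    return aggregates.vdg4_exams()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def small_cohort(config):
    """A reduced synthetic cohort for fast structural tests."""
    import dataclasses

    cfg = dataclasses.replace(config, n_sdc=120, n_ic=60, controls_per_cancer=3)
    return generate_cohort(cfg, seed=7)
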