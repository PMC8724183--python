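import pytest

import rehabpredict as rp


@pytest.fixture(scope="session")
def study_cohort():
    return rp.load_study_cohort()


@pytest.fixture(scope="session")
def study_labels(study_cohort):
    return rp.label_cohort(study_cohort)


@pytest.fixture(scope="session")
def clean_trial():
    """Unimpaired generated trial with default observation noise, plus truth."""
    return rp.gen_trial(rp.TrialGenParams(seed=0))


@pytest.fixture(scope="session")
def reference():
    ref, table = rp.gen_reference_population(seed=5)
    return ref, table
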