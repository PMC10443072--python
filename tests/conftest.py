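import numpy as np
import pytest

import vcfval as v


def identity_confusion():
    return tuple(map(tuple, np.eye(4)))


@pytest.fixture(scope="session")
def study_fixture():
    """The deterministic 1200-patient benchmark dataset."""
    return v.load_study_fixture()


@pytest.fixture(scope="session")
def study_tables(study_fixture):
    refs, index = study_fixture
    return v.all_tables(refs, index)


@pytest.fixture(scope="session")
def big_cohort():
    """A large default-parameter cohort shared across convergence tests."""
    return v.generate_cohort(v.default_config(n_patients=50_000, seed=20260919))


@pytest.fixture(scope="session")
def noiseless_kwargs():
    """Config overrides that make raters and the senior error-free."""
    return dict(
        rater_presence_agreement=1.0,
        rater_grade_confusion=identity_confusion(),
        perfect_senior=True,
    )


@pytest.fixture()
def small_cohort():
    return v.generate_cohort(v.default_config(n_patients=120, seed=7))
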