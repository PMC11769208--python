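import warnings

import pytest

from msdrisk import datasets
from msdrisk.pipeline import SubjectRecord
from msdrisk.simulate import CohortSpec, EffectSpec, generate_cohort, generate_cohort_trials


@pytest.fixture(scope="session")
def tables():
    return datasets.load_all_criteria()


@pytest.fixture(scope="session")
def curves():
    return datasets.load_canonical_curves()


@pytest.fixture(scope="session")
def neck_table(tables):
    return tables["neck"]


@pytest.fixture
def subject():
    return SubjectRecord(id="S1", sex="male", age=28.0, height=180.0,
                         weight=80.0, readiness_score=4,
                         scenario_mix={"no_belt": 1.0, "belt": 0.0})


#: Low-rate effect settings: feature ratios are resolution-independent, so
#: tests that only need the ratio structure run on short, sparse trials.
FAST_EFFECTS = dict(trial_duration_s=2.0, sample_rate_hz=5.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 12-subject cohort with trials, shared across tests."""
    spec = CohortSpec(n_subjects=12, male_fraction=0.5, seed=11)
    effects = EffectSpec(**FAST_EFFECTS)
    subjects = generate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trials = generate_cohort_trials(subjects, effects, seed=11)
    return subjects, trials
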