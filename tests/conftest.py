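import numpy as np
import pytest

from stressmon.features import extract_cohort_features
from stressmon.synthetic import conditions_for, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four-subject two-class cohort, 100 s per class (cheap, reused)."""
    return generate_cohort(4, conditions_for("mental"), seed=123,
                           duration_per_class=100.0)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
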