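import warnings

import pytest

from attnquality import (
    Cohort,
    ResponseEvent,
    ResponseSequence,
    extract_features,
    four_level_cohort_spec,
    generate_cohort,
)


@pytest.fixture()
def tiny_cohort():
    """Two hand-built participants with two tasks of two events each."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NoD far below protocol range
        return Cohort([
            ResponseSequence("alice", [
                [ResponseEvent("Y", True, 512.5), ResponseEvent("N", True, 640.0)],
                [ResponseEvent("I", False, 710.25), ResponseEvent("Y", True, 598.0)],
            ]),
            ResponseSequence("bob", [
                [ResponseEvent("N", False, 801.0), ResponseEvent("Y", True, 755.5)],
                [ResponseEvent("Y", True, 690.125), ResponseEvent("N", True, 610.0)],
            ]),
        ])


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Four latent quality groups, 10 participants each (fixed seed)."""
    return generate_cohort(four_level_cohort_spec(seed=7, n_per_group=10))


@pytest.fixture(scope="session")
def feature_table(synthetic_cohort):
    cohort, _ = synthetic_cohort
    return extract_features(cohort, dim=3)
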