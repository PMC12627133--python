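from itertools import product

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from catstrat import (
    DEFAULT_FIXTURE_SEED,
    fit_dataset,
    optimal_boundary,
    sample_category_set,
    simulate_cohort,
    task_distributions,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

ALL_TASKS = list(product(("auditory", "visual"), ("RB", "II")))


@pytest.fixture(scope="session")
def fixture_sets():
    """The four packaged training sets (fixture seed, 10/200 overlap)."""
    out = {}
    for modality, task in ALL_TASKS:
        distA, distB = task_distributions(modality, task)
        out[(modality, task)] = sample_category_set(
            distA, distB, 100, 10, seed=DEFAULT_FIXTURE_SEED
        )
    return out


@pytest.fixture(scope="session")
def fixture_bounds():
    return {
        (modality, task): optimal_boundary(*task_distributions(modality, task))
        for modality, task in ALL_TASKS
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-per-group cohort reused across integration tests."""
    return simulate_cohort(2, seed=11)


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    trials, _ = small_cohort
    return fit_dataset(trials, seed=5)
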