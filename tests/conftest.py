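import logging

import numpy as np
import pandas as pd
import pytest

from lbarace.fitting import FitConfig, fit_cohort, fit_subject
from lbarace.task import (
    build_task_schedule,
    sample_population,
    simulate_cohort,
    simulate_subject,
)

logging.getLogger("lbarace").setLevel(logging.ERROR)

# fast-but-adequate fitting settings for tests that only need a decent optimum
FAST_FIT = FitConfig(n_restarts=3, max_iter=800)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """6 synthetic subjects with ground truth, 96 trials each."""
    profiles = sample_population(6, seed=101)
    trials = simulate_cohort(profiles, seed=102)
    return profiles, trials


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    _, trials = small_cohort
    return fit_cohort(trials, "drift_model", FAST_FIT, seed=103)


@pytest.fixture(scope="session")
def one_subject():
    """A single subject's profile and 96-trial session."""
    profile = sample_population(1, seed=7)[0]
    schedule = build_task_schedule(seed=8)
    trials = simulate_subject(profile, schedule, seed=9)
    return profile, trials


@pytest.fixture(scope="session")
def one_subject_fit(one_subject):
    _, trials = one_subject
    return fit_subject(trials, "drift_model", FAST_FIT, seed=10)


@pytest.fixture(scope="session")
def rich_subject():
    """One subject with 960 trials (10 concatenated sessions)."""
    profile = sample_population(1, seed=31)[0]
    frames = [
        simulate_subject(profile, build_task_schedule(seed=40 + k), seed=60 + k)
        for k in range(10)
    ]
    return profile, pd.concat(frames, ignore_index=True)
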