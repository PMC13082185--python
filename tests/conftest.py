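"""Shared fixtures: small synthetic cohorts and a quick MCMC profile.

All fixtures are deterministic (fixed seeds) and deliberately small so
the full suite stays fast; statistical assertions use tolerances that
account for the reduced sizes.
"""

import numpy as np
import pytest

from vibereach.synthgen import CohortTruth, generate_cohort, task_design

#: fast sampling profile for unit tests (2 chains keeps R-hat defined)
QUICK = {"chains": 2, "draws": 400, "warmup": 400}


@pytest.fixture(scope="session")
def reported_truth() -> CohortTruth:
    """Truth with the reported condition effects at a reduced cohort size."""
    return CohortTruth(n_participants=8, seed=101)


@pytest.fixture(scope="session")
def null_truth() -> CohortTruth:
    return CohortTruth.null(n_participants=6, seed=202)


@pytest.fixture(scope="session")
def task1_trials(reported_truth):
    trials, _ = generate_cohort(reported_truth, task_design(1, reps=6))
    return trials


@pytest.fixture(scope="session")
def task2_trials(reported_truth):
    trials, _ = generate_cohort(reported_truth, task_design(2, reps=12))
    return trials


@pytest.fixture(scope="session")
def task3_cohort():
    truth = CohortTruth(
        n_participants=4, seed=303, tau_mean=0.050, tau_sd=0.004,
    )
    trials, tracked = generate_cohort(truth, task_design(3, reps=8))
    return truth, trials, tracked
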