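"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import expit

from oilab.agents import CohortSpec, simulate_cohort
from oilab.pipeline import prepare_analysis_table
from oilab.task_env import TaskConfig

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_cohort_tables():
    """One default 40-subject cohort, simulated once per session."""
    trial_log, probe_log, truth = simulate_cohort(CohortSpec(seed=11), TaskConfig())
    return trial_log, probe_log, truth


@pytest.fixture(scope="session")
def default_stay_table(default_cohort_tables):
    trial_log, probe_log, _ = default_cohort_tables
    stay, capacity, report = prepare_analysis_table(trial_log, probe_log)
    return stay, capacity, report


def make_glmm_stay_table(
    seed: int,
    n_subjects: int = 40,
    n_trials: int = 294,
    intercept: float = 0.2,
    b_prev: float = 0.6,
    b_interaction: float = 0.0,
    sd_intercept: float = 0.25,
    sd_prev: float = 0.25,
) -> pd.DataFrame:
    """Stay table drawn directly from the logistic mixed model.

    Used where a test needs data whose generating process *is* the
    regression model (self-consistency and coverage checks), as opposed to
    the behavioural agent simulator.
    """
    rng = np.random.default_rng(seed)
    cap = rng.standard_normal(n_subjects)
    cap = (cap - cap.mean()) / cap.std(ddof=1)
    u0 = rng.normal(0.0, sd_intercept, n_subjects)
    u1 = rng.normal(0.0, sd_prev, n_subjects)
    loads = ["none", "low", "high"]
    frames = []
    for s in range(n_subjects):
        prev = rng.integers(0, 2, n_trials)
        slope = b_prev + b_interaction * cap[s] + u1[s]
        psi = (intercept + u0[s]) + slope * (prev - 0.5)
        stay = (rng.random(n_trials) < expit(psi)).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{s:03d}",
                    "block": 1,
                    "trial": np.arange(1, n_trials + 1),
                    "load": [loads[t % 3] for t in range(n_trials)],
                    "stay": stay,
                    "prev_outcome": prev,
                    "capacity_z": cap[s],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
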