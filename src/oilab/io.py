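"""CSV schemas for trial and probe logs, with validating readers/writers.

Two tables flow through the pipeline:

* the *trial log* — one row per bandit offer (two offers per trial);
* the *probe log* — one row per change-detection probe, both the probes
  embedded in the dual task and the standalone capacity session.

Simulated cohorts additionally carry a *ground truth* table of generative
agent parameters used by recovery tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

TRIAL_LOG_COLUMNS = [
    "subject_id", "session", "block", "trial", "offer_index", "load",
    "card_left", "card_right", "chosen_card", "chosen_key", "rt_ms",
    "reward", "true_p_left", "true_p_right",
]

PROBE_LOG_COLUMNS = [
    "subject_id", "task", "block", "trial", "set_size", "load",
    "probe_same", "response_same", "correct", "rt_ms",
]

GROUND_TRUTH_COLUMNS = ["subject_id", "alpha_card", "alpha_key", "beta", "kappa"]

LOAD_LEVELS = ("none", "low", "high")
KEYS = ("left", "right")


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing columns: {missing}")


def validate_trial_log(df: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-log schema; returns the frame for chaining."""
    _require_columns(df, TRIAL_LOG_COLUMNS, "trial log")
    if not df["offer_index"].isin([1, 2]).all():
        raise SchemaError("trial log: offer_index must be 1 or 2")
    if not df["load"].isin(LOAD_LEVELS).all():
        raise SchemaError(f"trial log: load must be one of {LOAD_LEVELS}")
    if not df["chosen_key"].isin(KEYS).all():
        raise SchemaError(f"trial log: chosen_key must be one of {KEYS}")
    rewards = df["reward"].dropna()
    if not rewards.isin([0, 1]).all():
        raise SchemaError("trial log: reward must be 0 or 1")
    return df


def validate_probe_log(df: pd.DataFrame) -> pd.DataFrame:
    """Check the probe-log schema; returns the frame for chaining."""
    _require_columns(df, PROBE_LOG_COLUMNS, "probe log")
    if not df["task"].isin(["dual", "standalone"]).all():
        raise SchemaError("probe log: task must be 'dual' or 'standalone'")
    for col in ("probe_same", "response_same", "correct"):
        if not df[col].isin([0, 1]).all():
            raise SchemaError(f"probe log: {col} must be 0 or 1")
    if not (df["set_size"] >= 1).all():
        raise SchemaError("probe log: set_size must be >= 1")
    return df


def validate_ground_truth(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, GROUND_TRUTH_COLUMNS, "ground truth")
    return df


def write_trial_log(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_trial_log(df)
    df.to_csv(path, index=False)
    return path


def read_trial_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"load": str, "chosen_key": str})
    return validate_trial_log(df)


def write_probe_log(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_probe_log(df)
    df.to_csv(path, index=False)
    return path


def read_probe_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"task": str, "load": str})
    return validate_probe_log(df)


def frames_equal(a: pd.DataFrame, b: pd.DataFrame, float_cols: tuple[str, ...] = ()) -> bool:
    """Loose equality used by round-trip tests (CSV text formatting aside)."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        if col in float_cols or a[col].dtype.kind == "f":
            if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float), equal_nan=True):
                return False
        elif not (a[col].astype(str).to_numpy() == b[col].astype(str).to_numpy()).all():
            return False
    return True
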