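"""Model family and design matrices for the stay ~ previous-outcome GLMM.

Four nested models share one random-effects structure (subject-level
intercept, previous-outcome, load, and previous-outcome x load) and differ
only in fixed effects:

* ``M4_null``      — previous-outcome only;
* ``M3_capacity``  — + capacity and previous-outcome x capacity;
* ``M2_load``      — + load and previous-outcome x load (no capacity);
* ``M1_full``      — all terms including the triple interaction.

Coding: previous outcome centred at ±1/2 (so its coefficient is the
marginal effect), load as a three-level factor with sum-to-zero contrasts,
capacity z-scored.  An optional flag adds a per-subject learning-accuracy
covariate and its interaction with previous outcome (robustness analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, DataError

LOAD_ORDER = ("none", "low", "high")
# sum-to-zero contrasts: rows = levels in LOAD_ORDER, columns = (load1, load2)
_LOAD_CONTRASTS = {"none": (1.0, 0.0), "low": (0.0, 1.0), "high": (-1.0, -1.0)}

_BASE_TERMS = ("intercept", "prev", "load", "capacity", "accuracy")

MODEL_FIXED_TERMS: dict[str, tuple[str, ...]] = {
    "M4_null": ("intercept", "prev"),
    "M3_capacity": ("intercept", "prev", "capacity", "prev:capacity"),
    "M2_load": ("intercept", "prev", "load", "prev:load"),
    "M1_full": (
        "intercept", "prev", "load", "capacity",
        "prev:load", "prev:capacity", "load:capacity", "prev:load:capacity",
    ),
}

RANDOM_TERMS: tuple[str, ...] = ("intercept", "prev", "load", "prev:load")

MODEL_NAMES = tuple(MODEL_FIXED_TERMS)


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors; scales configurable for sensitivity runs.

    Fixed effects get Normal(0, ``fixed_scale``).  Random-effect standard
    deviations get a half-t(``random_sd_df``) with scale ``random_sd_scale``
    via a hierarchical inverse-Wishart on the covariance, which also keeps
    the implied correlation prior close to uniform.
    """

    fixed_scale: float = 1.0
    random_sd_scale: float = 1.0
    random_sd_df: int = 2

    def __post_init__(self) -> None:
        if self.fixed_scale <= 0 or self.random_sd_scale <= 0 or self.random_sd_df < 1:
            raise ConfigurationError("prior scales must be positive")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = RANDOM_TERMS
    priors: PriorSpec = field(default_factory=PriorSpec)
    coding: str = "sum"
    accuracy_covariate: bool = False


def build_model(
    name: str,
    priors: PriorSpec | None = None,
    coding: str = "sum",
    accuracy_covariate: bool = False,
) -> ModelSpec:
    """Construct one of the four nested model specifications."""
    if name not in MODEL_FIXED_TERMS:
        raise ConfigurationError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if coding != "sum":
        raise ConfigurationError("only sum-to-zero load coding is implemented")
    fixed = MODEL_FIXED_TERMS[name]
    if accuracy_covariate:
        fixed = fixed + ("accuracy", "prev:accuracy")
    return ModelSpec(
        name=name,
        fixed_terms=fixed,
        priors=priors or PriorSpec(),
        coding=coding,
        accuracy_covariate=accuracy_covariate,
    )


def _term_columns(term: str, table: pd.DataFrame) -> tuple[list[str], list[np.ndarray]]:
    """Columns for one (possibly interaction) term under the fixed coding."""
    names: list[list[str]] = []
    cols: list[list[np.ndarray]] = []
    n = len(table)
    for factor in term.split(":"):
        if factor == "intercept":
            names.append(["intercept"])
            cols.append([np.ones(n)])
        elif factor == "prev":
            names.append(["prev_outcome"])
            cols.append([table["prev_outcome"].to_numpy(dtype=float) - 0.5])
        elif factor == "load":
            loads = table["load"].to_numpy()
            unknown = set(loads) - set(LOAD_ORDER)
            if unknown:
                raise DataError(f"unknown load levels in data: {sorted(unknown)}")
            c1 = np.array([_LOAD_CONTRASTS[l][0] for l in loads])
            c2 = np.array([_LOAD_CONTRASTS[l][1] for l in loads])
            names.append(["load1", "load2"])
            cols.append([c1, c2])
        elif factor in ("capacity", "accuracy"):
            col = f"{factor}_z" if factor == "accuracy" else "capacity_z"
            if col not in table.columns:
                raise DataError(f"model term {factor!r} needs column {col!r} in the stay table")
            names.append([factor])
            cols.append([table[col].to_numpy(dtype=float)])
        else:
            raise ConfigurationError(f"unknown model term {factor!r}")
    out_names, out_cols = names[0], cols[0]
    for nm, cl in zip(names[1:], cols[1:]):
        out_names = [f"{a}:{b}" for a in out_names for b in nm]
        out_cols = [a * b for a in out_cols for b in cl]
    return out_names, out_cols


def design_matrices(spec: ModelSpec, table: pd.DataFrame):
    """Build fixed (X) and random (Z) design matrices from a stay table.

    Returns ``(X, x_names, Z, z_names, subj_codes, subj_ids)``.  The table
    needs columns subject_id, stay, prev_outcome, load, plus capacity_z
    (and accuracy_z) when the model references them.
    """
    required = {"subject_id", "stay", "prev_outcome", "load"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"stay table is missing columns {sorted(missing)}")
    x_names: list[str] = []
    x_cols: list[np.ndarray] = []
    for term in spec.fixed_terms:
        nm, cl = _term_columns(term, table)
        x_names.extend(nm)
        x_cols.extend(cl)
    z_names: list[str] = []
    z_cols: list[np.ndarray] = []
    for term in spec.random_terms:
        nm, cl = _term_columns(term, table)
        z_names.extend(nm)
        z_cols.extend(cl)
    X = np.column_stack(x_cols)
    Z = np.column_stack(z_cols) if z_cols else np.empty((len(table), 0))
    if not np.isfinite(X).all() or not np.isfinite(Z).all():
        bad = np.where(~np.isfinite(X).all(axis=1) | ~np.isfinite(Z).all(axis=1))[0]
        raise DataError(f"non-finite design rows at positions {bad[:10].tolist()}")
    subj_ids, subj_codes = np.unique(table["subject_id"].to_numpy(), return_inverse=True)
    return X, x_names, Z, z_names, subj_codes.astype(np.int64), subj_ids
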