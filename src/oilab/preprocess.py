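"""Data treatment: trial filters, participant exclusions, stay coding and
working-memory capacity estimation.

The analysis unit is the *trial*: each bandit trial contributes one stay
observation (did the second offer use the same response key as the first?)
predicted by the first offer's reward.  A trial is dropped whole if it is
the first of its block or if either offer's reaction time falls outside
(200, 4000) ms — strict inequalities, so boundary times are retained.
Participants are excluded for below-chance set-size-four change detection,
for losing more than 30% of their trials to the filters, or for pressing
the same response key on more than 80% of offers.

Capacity follows Cowan's K = N·(2·accuracy − 1) per set-size condition,
averaged across conditions; for the single-probe design with balanced
probes this is algebraically the hit-minus-false-alarm form N·(H − FA).
Negative K values are kept (they are informative for exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EstimationError
from .io import validate_probe_log, validate_trial_log

TRIAL_KEY = ["subject_id", "block", "trial"]


@dataclass(frozen=True)
class FilterConfig:
    rt_min: float = 200.0
    rt_max: float = 4000.0
    drop_first_trial_of_block: bool = True
    max_excluded_fraction: float = 0.30
    max_same_key_fraction: float = 0.80
    wm_chance_set_size: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.rt_min < self.rt_max):
            raise ConfigurationError("need 0 < rt_min < rt_max")
        for name in ("max_excluded_fraction", "max_same_key_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1)")


@dataclass
class ExclusionReport:
    """Trial-level removal statistics and per-subject exclusion flags."""

    n_trials_total: int = 0
    n_trials_removed: int = 0
    n_offers_total: int = 0
    n_offers_removed: int = 0
    per_subject: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)  # subject -> list of flag names

    @property
    def removed_fraction_trials(self) -> float:
        return self.n_trials_removed / self.n_trials_total if self.n_trials_total else 0.0

    @property
    def removed_fraction_offers(self) -> float:
        return self.n_offers_removed / self.n_offers_total if self.n_offers_total else 0.0

    @property
    def excluded_subjects(self) -> list[str]:
        return sorted(s for s, f in self.flags.items() if f)

    def to_dict(self) -> dict:
        return {
            "n_trials_total": self.n_trials_total,
            "n_trials_removed": self.n_trials_removed,
            "removed_fraction_trials": self.removed_fraction_trials,
            "n_offers_total": self.n_offers_total,
            "n_offers_removed": self.n_offers_removed,
            "removed_fraction_offers": self.removed_fraction_offers,
            "per_subject": self.per_subject,
            "flags": self.flags,
            "excluded_subjects": self.excluded_subjects,
        }


def filter_trials(trial_log: pd.DataFrame, config: FilterConfig = FilterConfig()):
    """Remove first-of-block trials and trials with out-of-range RTs.

    A trial is removed whole (both offers) if *either* offer's RT is
    strictly below ``rt_min``, strictly above ``rt_max``, or missing.
    Returns ``(retained_log, report)`` where the report carries trial- and
    offer-level removal counts, overall and per subject.
    """
    validate_trial_log(trial_log)
    df = trial_log.copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_offer = rt.isna() | (rt < config.rt_min) | (rt > config.rt_max)
    df["_bad_offer"] = bad_offer.to_numpy()
    first_trial = df.groupby(["subject_id", "block"])["trial"].transform("min")
    df["_first"] = (df["trial"] == first_trial) & config.drop_first_trial_of_block
    trial_bad = df.groupby(TRIAL_KEY)[["_bad_offer", "_first"]].transform("max")
    drop = (trial_bad["_bad_offer"] | trial_bad["_first"]).to_numpy()

    report = ExclusionReport(
        n_offers_total=len(df),
        n_offers_removed=int(drop.sum()),
    )
    trials = df[TRIAL_KEY].drop_duplicates()
    report.n_trials_total = len(trials)
    dropped_trials = df.loc[drop, TRIAL_KEY].drop_duplicates()
    report.n_trials_removed = len(dropped_trials)
    for sid, grp in df.groupby("subject_id"):
        n_tot = grp[TRIAL_KEY].drop_duplicates().shape[0]
        n_rem = grp.loc[
            (grp.groupby(TRIAL_KEY)[["_bad_offer", "_first"]].transform("max").any(axis=1)),
            TRIAL_KEY,
        ].drop_duplicates().shape[0]
        report.per_subject[str(sid)] = {
            "n_trials": int(n_tot),
            "n_removed": int(n_rem),
            "fraction_removed": n_rem / n_tot if n_tot else 0.0,
        }
    retained = df.loc[~drop].drop(columns=["_bad_offer", "_first"]).reset_index(drop=True)
    return retained, report


def exclude_participants(
    trial_log: pd.DataFrame,
    probe_log: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> ExclusionReport:
    """Apply the three participant-level exclusion rules (strict comparisons).

    (a) standalone change-detection accuracy at set size four below 0.5;
    (b) more than ``max_excluded_fraction`` of the subject's own trials
        removed by :func:`filter_trials`;
    (c) the same response key on more than ``max_same_key_fraction`` of
        retained offers.
    """
    validate_trial_log(trial_log)
    validate_probe_log(probe_log)
    trial_subjects = set(trial_log["subject_id"])
    probe_subjects = set(probe_log["subject_id"])
    if trial_subjects != probe_subjects:
        only = sorted(trial_subjects.symmetric_difference(probe_subjects))
        raise DataError(f"subjects present in only one log: {only}")

    retained, report = filter_trials(trial_log, config)
    standalone = probe_log[
        (probe_log["task"] == "standalone") & (probe_log["set_size"] == config.wm_chance_set_size)
    ]
    for sid in sorted(trial_subjects):
        flags = []
        probes = standalone[standalone["subject_id"] == sid]
        if len(probes) and probes["correct"].mean() < 0.5:
            flags.append("wm_below_chance")
        frac = report.per_subject.get(str(sid), {}).get("fraction_removed", 0.0)
        if frac > config.max_excluded_fraction:
            flags.append("too_many_bad_trials")
        offers = retained[retained["subject_id"] == sid]
        if len(offers):
            share = offers["chosen_key"].value_counts(normalize=True).max()
            if share > config.max_same_key_fraction:
                flags.append("key_repetition")
        report.flags[str(sid)] = flags
    return report


def code_stay(retained_log: pd.DataFrame) -> pd.DataFrame:
    """Build the stay-observation table from a retained trial log.

    stay = 1 iff the second offer's response key equals the first offer's;
    prev_outcome is the first offer's reward.  Trials missing either offer
    are dropped.
    """
    validate_trial_log(retained_log)
    wide = retained_log.pivot_table(
        index=TRIAL_KEY + ["load"],
        columns="offer_index",
        values=["chosen_key", "reward"],
        aggfunc="first",
    )
    both = wide.dropna(subset=[("chosen_key", 1), ("chosen_key", 2), ("reward", 1)])
    out = pd.DataFrame(
        {
            "subject_id": both.index.get_level_values("subject_id"),
            "block": both.index.get_level_values("block"),
            "trial": both.index.get_level_values("trial"),
            "load": both.index.get_level_values("load"),
            "stay": (both[("chosen_key", 2)] == both[("chosen_key", 1)]).astype(int).to_numpy(),
            "prev_outcome": both[("reward", 1)].astype(int).to_numpy(),
        }
    )
    return out.sort_values(TRIAL_KEY).reset_index(drop=True)


def cowan_k(accuracy: float | np.ndarray, set_size: int) -> float | np.ndarray:
    """Cowan's change-detection capacity K = N·(2·accuracy − 1)."""
    return set_size * (2.0 * np.asarray(accuracy, dtype=float) - 1.0)


def cowan_k_hit_fa(hit_rate: float, fa_rate: float, set_size: int) -> float:
    """Hit/false-alarm form K = N·(H − FA); identical to :func:`cowan_k`
    computed on balanced same/different probes."""
    return set_size * (hit_rate - fa_rate)


_EMBEDDED_SETS = {"low": 1, "high": 4}


def estimate_capacity(
    probe_log: pd.DataFrame, source: str = "standalone", min_probes_warn: int = 20
) -> pd.DataFrame:
    """Per-subject capacity estimates from change-detection probes.

    ``standalone``: K4 and K8 from the capacity session's set sizes 4 and 8,
    overall K their mean.  ``embedded``: the same formula on the dual-task
    probes at low load (set size 1) and high load (set size 4); no-load
    probes require no memory and are skipped.
    """
    validate_probe_log(probe_log)
    if source == "standalone":
        sub = probe_log[probe_log["task"] == "standalone"]
        conditions = {"K4": sub["set_size"] == 4, "K8": sub["set_size"] == 8}
        sizes = {"K4": 4, "K8": 8}
    elif source == "embedded":
        sub = probe_log[(probe_log["task"] == "dual") & (probe_log["load"] != "none")]
        conditions = {"K4": sub["load"] == "low", "K8": sub["load"] == "high"}
        sizes = {"K4": _EMBEDDED_SETS["low"], "K8": _EMBEDDED_SETS["high"]}
    else:
        raise EstimationError(f"unknown capacity source {source!r}")
    rows = []
    for sid, grp in sub.groupby("subject_id"):
        est = {"subject_id": sid, "source": source}
        for label, mask in conditions.items():
            probes = grp[mask.loc[grp.index]]
            if len(probes) == 0:
                raise EstimationError(f"subject {sid}: no probes for capacity condition {label}")
            est[label] = float(cowan_k(probes["correct"].mean(), sizes[label]))
            est[f"n_{label}"] = len(probes)
        est["K"] = 0.5 * (est["K4"] + est["K8"])
        rows.append(est)
    out = pd.DataFrame(rows)
    return out.sort_values("subject_id").reset_index(drop=True)


def compute_learning_accuracy(retained_log: pd.DataFrame) -> pd.DataFrame:
    """Fraction of offers on which the chosen card had the higher true
    reward probability; exact ties are excluded from the denominator."""
    validate_trial_log(retained_log)
    df = retained_log
    chose_left = df["chosen_card"] == df["card_left"]
    p_chosen = np.where(chose_left, df["true_p_left"], df["true_p_right"])
    p_other = np.where(chose_left, df["true_p_right"], df["true_p_left"])
    valid = p_chosen != p_other
    acc = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "correct": (p_chosen > p_other).astype(float),
            "valid": valid,
        }
    )
    out = (
        acc[acc["valid"]]
        .groupby("subject_id")["correct"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "accuracy", "size": "n_offers"})
        .reset_index()
    )
    return out


def standardize_capacity(estimates: pd.DataFrame, column: str = "K") -> pd.DataFrame:
    """z-score a per-subject covariate across included subjects (ddof=1)."""
    if len(estimates) < 2:
        raise DataError("standardization needs >= 2 subjects")
    values = estimates[column].to_numpy(dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise DataError(f"zero variance in {column}; cannot standardize")
    out = estimates.copy()
    out[f"{column}_z"] = (values - values.mean()) / sd
    return out
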