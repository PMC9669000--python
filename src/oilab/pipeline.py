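"""End-to-end orchestration: simulate -> preprocess -> fit -> compare -> report.

All randomness flows from ``RunConfig.seed`` through named substreams
(cohort generation, one per fitted model), so a run is reproducible
byte-for-byte.  Every stage validates its inputs and failures carry the
stage name plus the offending artifact path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import CohortSpec, simulate_cohort
from .errors import ConfigurationError, PipelineError
from .inference import (
    InferenceConfig,
    bayes_correlation,
    build_model,
    loo_stacking,
    marginal_means,
    sample_posterior,
    summarize_coefficient,
)
from .io import write_probe_log, write_trial_log
from .preprocess import (
    FilterConfig,
    code_stay,
    compute_learning_accuracy,
    estimate_capacity,
    exclude_participants,
    filter_trials,
    standardize_capacity,
)
from .task_env import TaskConfig

DEFAULT_MODELS = ("M1_full", "M2_load", "M3_capacity", "M4_null")


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    models: tuple[str, ...] = DEFAULT_MODELS
    output_dir: str = "oilab_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigurationError("select at least one model")


def _substream_seeds(seed: int, labels: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(int(seed))
    states = ss.generate_state(len(labels)).astype(np.int64) & 0x7FFFFFFF
    return {label: int(s) for label, s in zip(labels, states)}


def prepare_analysis_table(
    trial_log: pd.DataFrame,
    probe_log: pd.DataFrame,
    filters: FilterConfig = FilterConfig(),
):
    """Shared preprocessing: filters, exclusions, stay coding, covariates.

    Returns ``(stay_table, capacity, exclusion_report)`` where the stay
    table carries capacity_z and accuracy_z for the retained subjects.
    """
    report = exclude_participants(trial_log, probe_log, filters)
    excluded = set(report.excluded_subjects)
    retained_log, _ = filter_trials(trial_log, filters)
    retained_log = retained_log[~retained_log["subject_id"].isin(excluded)]
    stay = code_stay(retained_log)
    capacity = estimate_capacity(probe_log, source="standalone")
    capacity = capacity[~capacity["subject_id"].isin(excluded)].reset_index(drop=True)
    capacity = standardize_capacity(capacity, "K")
    accuracy = compute_learning_accuracy(retained_log)
    acc_vals = accuracy["accuracy"].to_numpy()
    acc_sd = acc_vals.std(ddof=1)
    accuracy["accuracy_z"] = (acc_vals - acc_vals.mean()) / acc_sd if acc_sd > 0 else 0.0
    stay = stay.merge(capacity[["subject_id", "K", "K_z"]], on="subject_id", how="inner")
    stay = stay.rename(columns={"K_z": "capacity_z"})
    stay = stay.merge(accuracy[["subject_id", "accuracy_z"]], on="subject_id", how="left")
    stay["accuracy_z"] = stay["accuracy_z"].fillna(0.0)
    return stay, capacity, report


@dataclass
class PipelineResult:
    paths: dict
    exclusions: dict
    summaries: dict  # model -> coefficient -> PosteriorSummary
    stacking: object
    marginal: dict
    correlation: object | None
    diagnostics: dict


def _library_versions() -> dict[str, str]:
    import arviz
    import numba
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
        "numba": numba.__version__,
    }


def run_pipeline(config: RunConfig, keep_draws: bool = False) -> PipelineResult:
    """Execute the full analysis and write all artifacts to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _substream_seeds(config.seed, ["cohort"] + [f"fit_{m}" for m in config.models])

    # --- simulate -------------------------------------------------------
    try:
        cohort = replace(config.cohort, seed=seeds["cohort"])
        trial_log, probe_log, truth = simulate_cohort(cohort, config.task)
        paths = {
            "trial_log": str(write_trial_log(trial_log, out / "trial_log.csv")),
            "probe_log": str(write_probe_log(probe_log, out / "probe_log.csv")),
            "ground_truth": str(out / "ground_truth.csv"),
        }
        truth.to_csv(out / "ground_truth.csv", index=False)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- preprocess -----------------------------------------------------
    try:
        stay, capacity, report = prepare_analysis_table(trial_log, probe_log, config.filters)
        stay.to_csv(out / "stay_observations.csv", index=False)
        capacity.to_csv(out / "capacity.csv", index=False)
        (out / "exclusions.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        paths.update(
            stay_observations=str(out / "stay_observations.csv"),
            capacity=str(out / "capacity.csv"),
            exclusions=str(out / "exclusions.json"),
        )
    except Exception as exc:
        raise PipelineError("preprocess", str(exc), artifact=paths.get("trial_log")) from exc

    # --- fit ------------------------------------------------------------
    fits, summaries, diagnostics = {}, {}, {}
    for name in config.models:
        try:
            model = build_model(name, priors=config.inference.priors)
            cfg = replace(config.inference, seed=seeds[f"fit_{name}"])
            draws = sample_posterior(model, stay, cfg)
            fits[name] = draws
            diagnostics[name] = draws.diagnostics
            summaries[name] = {
                coef: summarize_coefficient(
                    coef,
                    draws.samples(coef),
                    rope=config.inference.rope,
                    hdi_mass=config.inference.hdi_mass,
                    prior_sd=config.inference.priors.fixed_scale,
                )
                for coef in draws.names
            }
            if keep_draws:
                np.savez_compressed(
                    out / f"draws_{name}.npz",
                    beta=draws.beta,
                    sd=draws.sd,
                    loglik=draws.loglik,
                    names=np.array(draws.names),
                )
                paths[f"draws_{name}"] = str(out / f"draws_{name}.npz")
        except Exception as exc:
            raise PipelineError("fit", f"model {name}: {exc}", artifact=str(out / "stay_observations.csv")) from exc

    # --- compare --------------------------------------------------------
    try:
        stacking = loo_stacking(fits)
        (out / "stacking.json").write_text(json.dumps(stacking.to_dict(), indent=2, sort_keys=True))
        paths["stacking"] = str(out / "stacking.json")
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # --- marginal means and the capacity-learning correlation ----------
    focus = "M3_capacity" if "M3_capacity" in fits else config.models[0]
    marginal = marginal_means(fits[focus], at=(0, 1), hdi_mass=config.inference.hdi_mass)
    correlation = None
    if "prev_outcome" in fits[focus].sd_names:
        coefs = fits[focus].subject_coefficients("prev_outcome")
        merged = coefs.merge(capacity[["subject_id", "K", "K_z"]], on="subject_id")
        if "prev_outcome:capacity" in fits[focus].names:
            # a subject's previous-outcome effect includes the fixed
            # capacity-interaction contribution, not just the residual slope
            b_int = float(np.mean(fits[focus].samples("prev_outcome:capacity")))
            merged["coefficient"] = merged["coefficient"] + b_int * merged["K_z"]
        if len(merged) >= 3 and merged["coefficient"].std() > 0 and merged["K"].std() > 0:
            correlation = bayes_correlation(
                merged["K"].to_numpy(), merged["coefficient"].to_numpy(),
                rng=np.random.default_rng(seeds["cohort"] ^ 0x5EED),
            )

    # --- report ---------------------------------------------------------
    try:
        summary_payload = {
            model: {coef: s.to_dict() for coef, s in coefs.items()}
            for model, coefs in summaries.items()
        }
        payload = {
            "summaries": summary_payload,
            "marginal_means": marginal,
            "correlation": correlation.to_dict() if correlation else None,
            "diagnostics": diagnostics,
            "seed": config.seed,
        }
        (out / "summaries.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        paths["summaries"] = str(out / "summaries.json")
        report_md = render_report(config, summaries, stacking, marginal, correlation, diagnostics, report)
        (out / "report.md").write_text(report_md)
        paths["report"] = str(out / "report.md")
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    return PipelineResult(
        paths=paths,
        exclusions=report.to_dict(),
        summaries=summaries,
        stacking=stacking,
        marginal=marginal,
        correlation=correlation,
        diagnostics=diagnostics,
    )


def config_hash(config: RunConfig) -> str:
    from .config import run_config_to_dict

    blob = json.dumps(run_config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def render_report(config, summaries, stacking, marginal, correlation, diagnostics, exclusions) -> str:
    lines = [
        "# Outcome-irrelevant learning analysis report",
        "",
        f"- config hash: `{config_hash(config)}`",
        f"- seed: {config.seed}",
        f"- library versions: {_library_versions()}",
        f"- sampler diagnostics: {diagnostics}",
        f"- trials removed: {exclusions.removed_fraction_trials * 100:.2f}%"
        f" ({exclusions.n_trials_removed}/{exclusions.n_trials_total})",
        f"- excluded participants: {len(exclusions.excluded_subjects)} {exclusions.excluded_subjects}",
        "",
        "## Model comparison (PSIS-LOO stacking)",
        "",
    ]
    for name in stacking.names:
        lines.append(
            f"- {name}: weight {stacking.weights[name] * 100:.0f}%, "
            f"elpd {stacking.elpd[name]:.1f} (se {stacking.elpd_se[name]:.1f})"
        )
    lines.append("")
    for model, coefs in summaries.items():
        lines.append(f"## {model}")
        lines.append("")
        for coef, s in coefs.items():
            lines.append(f"- {coef}: {s.report_line()}")
        lines.append("")
    lines.append("## Marginal stay probability by previous outcome")
    lines.append("")
    for level, m in marginal.items():
        label = "rewarded" if level == 1 else "unrewarded"
        lines.append(
            f"- {label}: {m['median'] * 100:.1f}% "
            f"(HDI95% {m['hdi_low'] * 100:.1f}–{m['hdi_high'] * 100:.1f}%)"
        )
    lines.append("")
    if correlation is not None:
        lines.append(
            f"## Capacity–learning correlation\n\n- r: {correlation.report_line()}"
        )
        lines.append("")
    return "\n".join(lines)


def run_recovery(
    grid: list[dict],
    n_replicates: int,
    base_config: RunConfig,
    model_name: str = "M3_capacity",
) -> pd.DataFrame:
    """Parameter-recovery harness.

    ``grid`` is a list of CohortSpec field overrides (e.g.
    ``{"alpha_key_mean": 0.2, "alpha_key_link": 0.0}``).  Each cell is
    simulated ``n_replicates`` times with fresh seeds, preprocessed, and
    fitted with ``model_name``; the previous-outcome and interaction
    coefficients are recorded per replicate.  Sampler diagnostic issues
    are recorded per cell, never fatal.
    """
    if not grid:
        raise ConfigurationError("recovery grid must be nonempty")
    rows = []
    for cell, overrides in enumerate(grid):
        for rep in range(n_replicates):
            seed = int(
                np.random.SeedSequence([base_config.seed, cell, rep]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            cohort = replace(base_config.cohort, seed=seed, **overrides)
            trial_log, probe_log, truth = simulate_cohort(cohort, base_config.task)
            stay, capacity, _ = prepare_analysis_table(trial_log, probe_log, base_config.filters)
            model = build_model(model_name, priors=base_config.inference.priors)
            cfg = replace(base_config.inference, seed=seed ^ 0x7A11)
            draws = sample_posterior(model, stay, cfg)
            row = {"cell": cell, "replicate": rep, "seed": seed, **overrides}
            for coef in ("prev_outcome", "prev_outcome:capacity"):
                if coef in draws.names:
                    s = summarize_coefficient(
                        coef, draws.samples(coef), rope=base_config.inference.rope
                    )
                    key = "prev" if coef == "prev_outcome" else "interaction"
                    row[f"{key}_median"] = s.median
                    row[f"{key}_hdi_low"] = s.hdi_low
                    row[f"{key}_hdi_high"] = s.hdi_high
                    row[f"{key}_pd"] = s.pd
                    row[f"{key}_sign_recovered"] = bool(
                        s.hdi_high < 0 if s.median < 0 else s.hdi_low > 0
                    )
            row["rhat_max"] = draws.diagnostics["rhat_max"]
            row["rhat_ok"] = draws.diagnostics["rhat_max"] <= 1.01
            rows.append(row)
    return pd.DataFrame(rows)
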