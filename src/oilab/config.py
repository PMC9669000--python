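"""YAML (de)serialization of run configurations."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .agents import CohortSpec
from .errors import ConfigurationError
from .inference import InferenceConfig, PriorSpec
from .pipeline import RunConfig
from .preprocess import FilterConfig
from .task_env import TaskConfig, WalkConfig


def run_config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["task"]["load_schedule"] = list(config.task.load_schedule)
    d["models"] = list(config.models)
    return d


def save_run_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(run_config_to_dict(config), sort_keys=True))
    return path


def _build(cls, data: dict | None, **nested):
    data = dict(data or {})
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    data.update(nested)
    return cls(**data)


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    task_data = dict(data.pop("task", {}) or {})
    walk_data = dict(task_data.pop("walk", None) or {})
    for key in ("bounds", "init_range"):
        if walk_data.get(key) is not None:
            walk_data[key] = tuple(walk_data[key])
    walk = _build(WalkConfig, walk_data)
    if "bounds" in task_data or "init_range" in task_data:
        raise ConfigurationError("walk parameters belong under task.walk")
    if "load_schedule" in task_data and task_data["load_schedule"] is not None:
        task_data["load_schedule"] = tuple(task_data["load_schedule"])
    task = _build(TaskConfig, task_data, walk=walk)
    cohort = _build(CohortSpec, data.pop("cohort", {}))
    filters = _build(FilterConfig, data.pop("filters", {}))
    inf_data = dict(data.pop("inference", {}) or {})
    priors = _build(PriorSpec, inf_data.pop("priors", None))
    if "rope" in inf_data and inf_data["rope"] is not None:
        inf_data["rope"] = tuple(inf_data["rope"])
    inference = _build(InferenceConfig, inf_data, priors=priors)
    if "models" in data and data["models"] is not None:
        data["models"] = tuple(data["models"])
    if "seed" not in data:
        raise ConfigurationError("an explicit seed is mandatory in the run config")
    return _build(RunConfig, data, task=task, cohort=cohort, filters=filters, inference=inference)


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return run_config_from_dict(data)
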