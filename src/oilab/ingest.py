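"""Map externally deposited trial-level tables into the internal schemas.

The mapping file (YAML) names the external files and translates their
column names:

.. code-block:: yaml

    trial_log:
      file: rl_trials.csv
      columns:            # internal_name: external_name
        subject_id: subject
        chosen_key: key_pressed
    probe_log:
      file: wm_probes.csv
      columns: {}

Unlisted columns are assumed to already carry their internal names.  A
validation report lists external columns that were not used.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import IngestionError
from .io import (
    PROBE_LOG_COLUMNS,
    TRIAL_LOG_COLUMNS,
    validate_probe_log,
    validate_trial_log,
)

_DEFAULT_FILES = {"trial_log": "trial_log.csv", "probe_log": "probe_log.csv"}


def _ingest_table(path: Path, columns_map: dict, required: list[str], validator, label: str):
    if not path.exists():
        raise IngestionError(f"{label}: file not found: {path}")
    raw = pd.read_csv(path)
    rename = {ext: internal for internal, ext in (columns_map or {}).items()}
    df = raw.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestionError(f"{label}: missing mandatory columns {missing}")
    unmapped = [c for c in df.columns if c not in required]
    validator(df[required])
    return df[required].copy(), unmapped


def ingest_external(path: str | Path, mapping: str | Path | dict | None = None):
    """Ingest a deposited data directory.

    Returns ``(trial_log, probe_log, report)`` where the report records the
    files read and any unmapped external columns.
    """
    root = Path(path)
    if isinstance(mapping, (str, Path)):
        mapping = yaml.safe_load(Path(mapping).read_text())
    mapping = mapping or {}
    report: dict = {"unmapped": {}, "files": {}}
    tables = {}
    for label, required, validator in (
        ("trial_log", TRIAL_LOG_COLUMNS, validate_trial_log),
        ("probe_log", PROBE_LOG_COLUMNS, validate_probe_log),
    ):
        section = mapping.get(label, {}) or {}
        file_path = root / section.get("file", _DEFAULT_FILES[label])
        df, unmapped = _ingest_table(
            file_path, section.get("columns", {}), required, validator, label
        )
        tables[label] = df
        report["files"][label] = str(file_path)
        report["unmapped"][label] = unmapped
    return tables["trial_log"], tables["probe_log"], report
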