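"""Readers, writers and run configuration.

Long-format CSV is the single interchange format for diary observations
(columns ``patient_id, subgroup, set, period, order, arm, day, outcome``);
JSON carries configurations and results.  Every stochastic output records
the master seed and a hash of the configuration that produced it, so two
runs with identical config and seed yield byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SERIES_COLUMNS

KEY_COLUMNS = ["patient_id", "set", "period", "day", "arm"]


class SchemaError(ValueError):
    """Input table violates the expected schema."""


def load_series(path) -> pd.DataFrame:
    """Load and validate a long-format diary series CSV.

    Checks the fixed column set, numeric outcomes (offending row numbers
    are reported), arm labels, and duplicate observation keys.
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    outcome = pd.to_numeric(df["outcome"], errors="coerce")
    bad = df.index[outcome.isna()].tolist()
    if bad:
        raise SchemaError(f"non-numeric outcome in rows {bad[:10]}")
    df["outcome"] = outcome
    bad_arm = set(df["arm"].unique()) - {"active", "placebo"}
    if bad_arm:
        raise SchemaError(f"unknown arm labels: {sorted(bad_arm)}")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        rows = df.index[dup].tolist()
        raise SchemaError(f"duplicate (patient, set, period, day, arm) keys in rows {rows[:10]}")
    return df[SERIES_COLUMNS + [c for c in df.columns if c not in SERIES_COLUMNS]]


def save_series(df: pd.DataFrame, path) -> None:
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df.to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=_jsonify)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
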