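"""Trial-log CSV and configuration file handling.

The trial-log schema is one header row plus one row per trial, UTF-8,
comma-delimited, '.' decimal separator; missing response/rt/correct are
empty fields. Config files (YAML or JSON) mirror ``TaskConfig`` field
names under a ``task`` block, observer parameter sets under a named
``groups`` list.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .design import TRIAL_LOG_COLUMNS, TaskConfig
from .errors import ConfigError, SchemaError
from .observer import ObserverParams

_VALID_TRUTH = {"same", "different"}
_VALID_RESPONSE = {"same", "different", "none", ""}
_VALID_LABEL = {"plus", "minus", "neutral", "excluded", ""}


def write_trial_log(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["correct"] = out["correct"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial log; raises SchemaError with line items."""
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot parse {path}: {exc}") from exc

    errors: List[str] = []
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}", errors=[f"header: missing {missing}"])
    df = df[TRIAL_LOG_COLUMNS].copy()

    for col in ("f1_hz", "f2_hz", "diff_percent", "rt_ms", "correct"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("block_index", "trial_index"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["response"] = df["response"].astype(str).replace("nan", "")
    df["bias_label"] = df["bias_label"].astype(str).replace("nan", "")
    df["truth"] = df["truth"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = df["group"].astype(str)

    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        if row.truth not in _VALID_TRUTH:
            errors.append(f"line {i}: truth {row.truth!r} not in {sorted(_VALID_TRUTH)}")
        if row.response not in _VALID_RESPONSE:
            errors.append(f"line {i}: response {row.response!r} invalid")
        if row.bias_label not in _VALID_LABEL:
            errors.append(f"line {i}: bias_label {row.bias_label!r} invalid")
        if not (row.f1_hz > 0) or not (row.f2_hz > 0):
            errors.append(f"line {i}: non-positive or missing frequency")
        elif not np.isclose(row.f2_hz, row.f1_hz * (1 + row.diff_percent / 100.0), rtol=1e-6):
            errors.append(f"line {i}: f2 != f1 * (1 + diff/100)")
        if len(errors) >= 50:
            errors.append("... (further errors suppressed)")
            break
    if errors:
        raise SchemaError(f"{path}: {len(errors)} schema violation(s)", errors=errors)
    return df


def load_config(path) -> dict:
    """Load a YAML/JSON config file into a plain dict."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def parse_config(raw: dict) -> Tuple[TaskConfig, List[tuple], Optional[int]]:
    """(TaskConfig, group_specs, seed) from a raw config dict.

    ``groups`` entries carry ``name``, ``n_subjects`` and an
    ``observer`` block mirroring ObserverParams field names
    (``rt_model`` as a [type, mu, sigma] list).
    """
    task = TaskConfig.from_dict(raw.get("task", {}))
    specs = []
    for g in raw.get("groups", []):
        try:
            name, n = g["name"], int(g["n_subjects"])
        except KeyError as exc:
            raise ConfigError(f"group entry missing {exc}") from exc
        obs = dict(g.get("observer", {}))
        if "rt_model" in obs and obs["rt_model"] is not None:
            obs["rt_model"] = tuple(obs["rt_model"])
        specs.append((name, n, ObserverParams(**obs)))
    seed = raw.get("seed")
    return task, specs, seed


def config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
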