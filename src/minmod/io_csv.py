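"""CSV / JSON / config file handling.

Time series travel as RFC-4180 UTF-8 CSV with the fixed header
``time_min,glucose_mg_dl,insulin_uU_ml``; results as JSON with sorted keys
(byte-identical across repeated runs).  Configs may be JSON or simple
``key=value`` text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .estimation import IVGTTRecord, Protocol

__all__ = [
    "IVGTT_COLUMNS",
    "read_ivgtt_csv",
    "write_ivgtt_csv",
    "read_config",
    "write_json",
]

IVGTT_COLUMNS = ("time_min", "glucose_mg_dl", "insulin_uU_ml")


def read_ivgtt_csv(path, subject_id: str | None = None) -> IVGTTRecord:
    """Read and validate one IVGTT record.

    Errors name the offending column or 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise DataError(f"cannot parse {path}: {e}") from e
    for col in IVGTT_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    sub = df[list(IVGTT_COLUMNS)]
    if sub.isna().any().any():
        row = int(sub.isna().any(axis=1).idxmax()) + 1
        raise DataError(f"{path}: missing value at data row {row}")
    t = sub["time_min"].to_numpy(dtype=float)
    g = sub["glucose_mg_dl"].to_numpy(dtype=float)
    i = sub["insulin_uU_ml"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise DataError(f"{path}: time not strictly increasing at data row {bad[0] + 2}")
    for name, v in (("glucose", g), ("insulin", i)):
        nonpos = np.nonzero(v <= 0)[0]
        if nonpos.size:
            raise DataError(f"{path}: non-positive {name} at data row {nonpos[0] + 1}")
    return IVGTTRecord(
        subject_id=subject_id or path.stem,
        times=t,
        glucose=g,
        insulin=i,
        protocol=Protocol(),
    )


def write_ivgtt_csv(record: IVGTTRecord, path) -> None:
    df = pd.DataFrame(
        {
            "time_min": record.times,
            "glucose_mg_dl": record.glucose,
            "insulin_uU_ml": record.insulin,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config(path) -> dict:
    """Read a JSON or key=value configuration file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8").strip()
    if text.startswith("{"):
        try:
            return json.loads(text)
        except json.JSONDecodeError as e:
            raise DataError(f"{path}: invalid JSON config: {e}") from e
    config = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DataError(f"{path}: line {lineno}: expected key=value, got {line!r}")
        key, _, val = line.partition("=")
        config[key.strip()] = _coerce(val.strip())
    return config


def write_json(obj: dict, path) -> None:
    """Deterministic JSON output (sorted keys, fixed layout)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
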