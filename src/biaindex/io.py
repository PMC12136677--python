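"""Cohort CSV and generator-config file handling.

The cohort CSV uses the fixed, case-sensitive header of
:data:`biaindex.schema.COHORT_COLUMNS`, UTF-8, comma delimiters and decimal
points.  Numbers are serialized at repr precision so write → read round-trips
are exact.  Generator configurations are stored as TOML.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import COHORT_COLUMNS, SchemaError, validate_cohort
from .simulate import GeneratorConfig

__all__ = ["read_cohort", "write_cohort", "read_config", "write_config"]


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a cohort CSV; returns ``(valid_table, rejections)``.

    Rows violating the record invariants are collected in the rejection
    report (original row number, subject id, reason) rather than raising;
    a missing mandatory column or an empty file is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype={"subject_id": str, "sex": str, "weight_status": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty cohort file: {path}") from exc
    if raw.empty and len(raw.columns) == 0:
        raise SchemaError(f"empty cohort file: {path}")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    raw = raw[COHORT_COLUMNS]
    return validate_cohort(raw)


def write_cohort(table: pd.DataFrame, path) -> Path:
    """Write a cohort table in schema column order at full precision."""
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cannot write cohort, missing column(s): {', '.join(missing)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    table[COHORT_COLUMNS].to_csv(path, index=False)
    return path


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value).__name__} to TOML")


def _emit_table(name: str, data: dict, out: list[str]) -> None:
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    if name:
        out.append(f"[{name}]")
    for k, v in scalars.items():
        key = k if k.replace("_", "").isalnum() else f'"{k}"'
        out.append(f"{key} = {_toml_scalar(v)}")
    if scalars or not name:
        out.append("")
    for k, v in tables.items():
        sub = f"{name}.{_quote_key(k)}" if name else _quote_key(k)
        _emit_table(sub, v, out)


def _quote_key(k: str) -> str:
    return k if k.replace("_", "").isalnum() else f'"{k}"'


def write_config(config: GeneratorConfig, path) -> Path:
    """Serialize a generator config to TOML (round-trippable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out: list[str] = []
    _emit_table("", config.model_dump(mode="json"), out)
    path.write_text("\n".join(out).strip() + "\n", encoding="utf-8")
    return path


def read_config(path) -> GeneratorConfig:
    """Load a generator config from TOML."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "age_range" in data:
        data["age_range"] = tuple(data["age_range"])
    return GeneratorConfig(**data)
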