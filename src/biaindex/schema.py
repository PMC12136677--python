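"""Cohort table schema and per-record validation.

A cohort is exchanged between stages as a :class:`pandas.DataFrame` with the
fixed column set of :data:`COHORT_COLUMNS` (one row per subject).  Individual
rows are validated against :class:`BioimpedanceRecord`, which encodes the
physical and physiological constraints a tetrapolar 50 kHz whole-body
measurement must satisfy.
"""

from __future__ import annotations

import math
from typing import Optional

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

#: Exact, case-sensitive column order of the cohort CSV schema.
COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "weight_status",
    "Z_ohm",
    "R_ohm",
    "Xc_ohm",
    "Xcc_ohm",
    "ECM_kg",
    "TBW_L",
    "ICW_L",
    "ECW_L",
]

SEX_LEVELS = ("female", "male")
STATUS_LEVELS = ("underweight", "normal", "overweight")

#: Relative tolerance for the impedance triangle and water-balance identities.
IDENTITY_RTOL = 1e-6

AGE_MIN, AGE_MAX = 2.0, 18.0


class SchemaError(ValueError):
    """Raised for structural problems (missing columns, empty files)."""


class BioimpedanceRecord(BaseModel):
    """One subject's raw measurements and anthropometrics.

    ``R_ohm`` may be absent (``None``); downstream derivation recovers it from
    ``sqrt(Z² − Xc²)``.  When all three of Z, R, Xc are present they must
    satisfy the impedance-triangle identity ``Z² = R² + Xc²``, and the water
    compartments must balance (``ICW + ECW = TBW``).
    """

    subject_id: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    weight_status: str
    Z_ohm: float
    R_ohm: Optional[float] = None
    Xc_ohm: float
    Xcc_ohm: float
    ECM_kg: float
    TBW_L: float
    ICW_L: float
    ECW_L: float

    @field_validator("sex")
    @classmethod
    def _sex_level(cls, v: str) -> str:
        if v not in SEX_LEVELS:
            raise ValueError(f"unknown sex level {v!r}")
        return v

    @field_validator("weight_status")
    @classmethod
    def _status_level(cls, v: str) -> str:
        if v not in STATUS_LEVELS:
            raise ValueError(f"unknown weight_status level {v!r}")
        return v

    @field_validator("age")
    @classmethod
    def _age_range(cls, v: float) -> float:
        if not (AGE_MIN <= v <= AGE_MAX):
            raise ValueError(f"age {v} outside cohort range [{AGE_MIN}, {AGE_MAX}] years")
        return v

    @field_validator("height_cm", "weight_kg", "Z_ohm")
    @classmethod
    def _strictly_positive(cls, v: float, info) -> float:
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be positive and finite, got {v}")
        return v

    @field_validator("Xc_ohm", "Xcc_ohm", "ECM_kg", "TBW_L", "ICW_L", "ECW_L")
    @classmethod
    def _nonnegative(cls, v: float, info) -> float:
        if not (v >= 0) or not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be non-negative and finite, got {v}")
        return v

    @field_validator("R_ohm")
    @classmethod
    def _r_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if not (v > 0):
            raise ValueError(f"R_ohm must be positive, got {v}")
        return v

    @model_validator(mode="after")
    def _identities(self) -> "BioimpedanceRecord":
        if self.R_ohm is not None:
            lhs = self.Z_ohm**2
            rhs = self.R_ohm**2 + self.Xc_ohm**2
            if abs(lhs - rhs) > IDENTITY_RTOL * max(lhs, rhs):
                raise ValueError(
                    f"impedance triangle violated: Z²={lhs:.6g} vs R²+Xc²={rhs:.6g}"
                )
        else:
            if self.Xc_ohm > self.Z_ohm * (1 + IDENTITY_RTOL):
                raise ValueError("Xc_ohm exceeds Z_ohm; R cannot be recovered")
        balance = self.ICW_L + self.ECW_L
        if abs(balance - self.TBW_L) > IDENTITY_RTOL * max(balance, self.TBW_L, 1e-300):
            raise ValueError(
                f"water balance violated: ICW+ECW={balance:.6g} vs TBW={self.TBW_L:.6g}"
            )
        return self


def validate_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate each row against :class:`BioimpedanceRecord`.

    Returns ``(valid, rejections)`` where ``valid`` preserves the input row
    order and ``rejections`` has one row per invalid record with its original
    positional ``row`` number and a human-readable ``reason``.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    keep, rejects = [], []
    for pos, (_, row) in enumerate(table.iterrows()):
        payload = row[COHORT_COLUMNS].to_dict()
        payload["subject_id"] = str(payload["subject_id"])
        try:
            BioimpedanceRecord(**payload)
        except Exception as exc:  # pydantic.ValidationError or ValueError
            rejects.append({"row": pos, "subject_id": payload["subject_id"], "reason": _brief(exc)})
            continue
        keep.append(pos)
    valid = table.iloc[keep].reset_index(drop=True)
    rejections = pd.DataFrame(rejects, columns=["row", "subject_id", "reason"])
    return valid, rejections


def _brief(exc: Exception) -> str:
    """Flatten a pydantic ValidationError into a short single-line reason."""
    try:
        errors = exc.errors()  # type: ignore[attr-defined]
        return "; ".join(e["msg"].removeprefix("Value error, ") for e in errors)
    except AttributeError:
        return str(exc)
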