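"""Core bioparameter formulas.

Implements the quantities derived from a single-frequency (50 kHz) tetrapolar
bioimpedance measurement:

* impedance magnitude ``|Z| = sqrt(R² + Xc²)``,
* phase angle ``θ = arctan(Xc / R)`` in degrees,
* sex-specific Kotler total-body-water (TBW) prediction from height,
  impedance magnitude and weight,
* the specific resistance and reactance indexes
  ``I_r = TBW · R / height²`` and ``I_Xc = TBW · Xc / height²``,
  evaluated with TBW in m³ and height in m so that both indexes carry
  units of Ω·m and sit near 7 Ω·m / 1 Ω·m in a pediatric cohort.

All scalar operations are numpy-vectorized and accept arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import COHORT_COLUMNS

__all__ = [
    "DomainError",
    "impedance_magnitude",
    "phase_angle_deg",
    "tbw_kotler",
    "specific_indexes",
    "derive_all",
    "DeriveResult",
    "DERIVED_COLUMNS",
]


class DomainError(ValueError):
    """An input lies outside the physical domain of a formula."""


# Kotler prediction coefficients: TBW = a · height^p / Z^q / d + b · weight + c
# (height in cm, Z in Ω, weight in kg, TBW in liters).
_KOTLER = {
    "male": dict(a=0.58, p=1.62, q=0.70, d=1.35, b=0.32, c=-3.66),
    "female": dict(a=0.76, p=1.99, q=0.58, d=18.91, b=0.14, c=-0.86),
}

DERIVED_COLUMNS = ["tbw_kotler_L", "theta_deg", "theta_dataset_deg", "I_r", "I_Xc"]


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr > 0)):
        raise DomainError(f"{name} must be strictly positive")
    return arr


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr >= 0)):
        raise DomainError(f"{name} must be non-negative")
    return arr


def impedance_magnitude(r_ohm, xc_ohm):
    """|Z| in Ω from resistance and capacitive reactance."""
    r = _check_positive("R_ohm", r_ohm)
    xc = _check_nonnegative("Xc_ohm", xc_ohm)
    out = np.hypot(r, xc)
    return float(out) if out.ndim == 0 else out


def phase_angle_deg(r_ohm, xc_ohm):
    """Phase angle θ = arctan(Xc/R) in degrees, in [0, 90)."""
    r = _check_positive("R_ohm", r_ohm)
    xc = _check_nonnegative("Xc_ohm", xc_ohm)
    out = np.degrees(np.arctan2(xc, r))
    return float(out) if out.ndim == 0 else out


def tbw_kotler(sex, height_cm, weight_kg, z_ohm):
    """Sex-specific Kotler total-body-water prediction in liters.

    Accepts scalars or aligned arrays; ``sex`` entries must be ``"female"``
    or ``"male"``.  The result may be non-positive for physiologically
    implausible inputs; callers decide how to flag that (see
    :func:`derive_all`).
    """
    h = _check_positive("height_cm", height_cm)
    w = _check_positive("weight_kg", weight_kg)
    z = _check_positive("Z_ohm", z_ohm)
    sex_arr = np.asarray(sex)
    h, w, z, sex_arr = np.broadcast_arrays(h, w, z, sex_arr)
    out = np.empty(h.shape, dtype=float)
    seen = np.zeros(h.shape, dtype=bool)
    for level, k in _KOTLER.items():
        m = sex_arr == level
        out[m] = k["a"] * h[m] ** k["p"] / z[m] ** k["q"] / k["d"] + k["b"] * w[m] + k["c"]
        seen |= m
    if not seen.all():
        bad = np.unique(sex_arr[~seen])
        raise DomainError(f"unknown sex level(s): {bad.tolist()}")
    return float(out) if out.ndim == 0 else out


def specific_indexes(tbw_L, r_ohm, xc_ohm, height_cm):
    """Specific resistance and reactance indexes ``(I_r, I_Xc)`` in Ω·m.

    The water volume enters in m³ (1 L = 1e-3 m³) and height in m, the
    convention under which the indexes take magnitudes of a few Ω·m.
    """
    tbw = _check_nonnegative("TBW_L", tbw_L)
    r = _check_positive("R_ohm", r_ohm)
    xc = _check_nonnegative("Xc_ohm", xc_ohm)
    h = _check_positive("height_cm", height_cm)
    h_m = h / 100.0
    tbw_m3 = tbw / 1000.0
    i_r = tbw_m3 * r / h_m**2
    i_xc = tbw_m3 * xc / h_m**2
    if i_r.ndim == 0:
        return float(i_r), float(i_xc)
    return i_r, i_xc


@dataclass
class DeriveResult:
    """Outcome of :func:`derive_all`.

    ``table`` holds the accepted input rows (original order, original columns)
    with the derived columns appended; ``rejections`` lists excluded rows with
    reasons; ``warnings`` counts soft flags that did not exclude a row.
    """

    table: pd.DataFrame
    rejections: pd.DataFrame
    warnings: dict = field(default_factory=dict)


def derive_all(cohort: pd.DataFrame) -> DeriveResult:
    """Attach TBW_Kotler, phase angles and specific indexes per record.

    Two phase angles are reported: ``theta_deg`` from the raw reactance Xc
    (the textbook definition) and ``theta_dataset_deg`` from the corrected
    reactance Xcc, the convention under which the cohort's stratified phase
    statistics are quoted.  The indexes use the raw R and Xc.

    Records with missing R have it recovered as ``sqrt(Z² − Xc²)`` (counted
    in ``warnings["r_recovered"]``).  Records yielding non-positive TBW are
    excluded and reported, not silently dropped; phase angles at or above
    45° are flagged as implausible for an infant–juvenile cohort but kept.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise DomainError(f"cohort table missing column(s): {', '.join(missing)}")
    n = len(cohort)
    warnings = {"r_recovered": 0, "tbw_nonpositive": 0, "theta_ge_45": 0}
    if n == 0:
        empty = cohort.copy()
        for c in DERIVED_COLUMNS:
            empty[c] = pd.Series(dtype=float)
        return DeriveResult(empty, pd.DataFrame(columns=["row", "subject_id", "reason"]), warnings)

    work = cohort.reset_index(drop=True).copy()
    rejects = []

    bad = ~(
        (work["Z_ohm"] > 0)
        & (work["height_cm"] > 0)
        & (work["weight_kg"] > 0)
        & (work["Xc_ohm"] >= 0)
    )
    for pos in np.flatnonzero(bad.to_numpy()):
        rejects.append(
            {
                "row": int(pos),
                "subject_id": str(work.at[pos, "subject_id"]),
                "reason": "non-positive Z/height/weight or negative Xc",
            }
        )
    ok = ~bad.to_numpy()

    r = work["R_ohm"].to_numpy(dtype=float).copy()
    z = work["Z_ohm"].to_numpy(dtype=float)
    xc = work["Xc_ohm"].to_numpy(dtype=float)
    recover = np.isnan(r) & ok
    if recover.any():
        # clip guards float cancellation for Xc ≈ Z
        r[recover] = np.sqrt(np.clip(z[recover] ** 2 - xc[recover] ** 2, 0.0, None))
        warnings["r_recovered"] = int(recover.sum())
    bad_r = ok & ~(r > 0)
    for pos in np.flatnonzero(bad_r):
        rejects.append(
            {
                "row": int(pos),
                "subject_id": str(work.at[pos, "subject_id"]),
                "reason": "resistance missing and not recoverable from Z, Xc",
            }
        )
    ok &= ~bad_r

    tbw = np.full(n, np.nan)
    theta = np.full(n, np.nan)
    theta_ds = np.full(n, np.nan)
    i_r = np.full(n, np.nan)
    i_xc = np.full(n, np.nan)
    if ok.any():
        sex = work["sex"].to_numpy()
        h = work["height_cm"].to_numpy(dtype=float)
        w = work["weight_kg"].to_numpy(dtype=float)
        xcc = work["Xcc_ohm"].to_numpy(dtype=float)
        tbw[ok] = tbw_kotler(sex[ok], h[ok], w[ok], z[ok])
        theta[ok] = phase_angle_deg(r[ok], xc[ok])
        theta_ds[ok] = phase_angle_deg(r[ok], xcc[ok])

        implausible = ok & ~(tbw > 0)
        if implausible.any():
            warnings["tbw_nonpositive"] = int(implausible.sum())
            for pos in np.flatnonzero(implausible):
                rejects.append(
                    {
                        "row": int(pos),
                        "subject_id": str(work.at[pos, "subject_id"]),
                        "reason": "implausible physiology: Kotler TBW <= 0",
                    }
                )
            ok &= ~implausible
        warnings["theta_ge_45"] = int((theta[ok] >= 45.0).sum())
        i_r[ok], i_xc[ok] = specific_indexes(tbw[ok], r[ok], xc[ok], h[ok])

    work["tbw_kotler_L"] = tbw
    work["theta_deg"] = theta
    work["theta_dataset_deg"] = theta_ds
    work["I_r"] = i_r
    work["I_Xc"] = i_xc
    table = work.iloc[np.flatnonzero(ok)].reset_index(drop=True)
    rejections = pd.DataFrame(
        sorted(rejects, key=lambda d: d["row"]), columns=["row", "subject_id", "reason"]
    )
    return DeriveResult(table, rejections, warnings)
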