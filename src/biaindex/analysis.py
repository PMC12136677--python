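"""Stratified summaries, ordering checks and trend lines.

Reproduces the cohort-level descriptive analyses: medians/means of the
specific indexes and phase angle by sex and by weight status, the
pass/fail evaluation of the expected stratum orderings, least-squares trend
lines in the (I_r, I_Xc) plane per subject group, and the predicted-vs-true
export table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PARAMETER_COLUMNS",
    "stratified_summary",
    "ordering_check",
    "TrendLine",
    "fit_group_trends",
    "predicted_vs_true_table",
]

#: Analysis parameter -> column in a derived cohort table.  ``theta`` is the
#: dataset-convention phase angle, the one whose stratified statistics the
#: reference cohort reports.
PARAMETER_COLUMNS = {
    "I_r": "I_r",
    "I_Xc": "I_Xc",
    "theta": "theta_dataset_deg",
}

MAD_SCALE = 1.4826  # consistent with the SD under normality


def stratified_summary(
    table: pd.DataFrame,
    by: str,
    statistic: str = "median",
    parameters: Iterable[str] = ("I_r", "I_Xc", "theta"),
    predictions: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row per (stratum level × parameter × source).

    ``statistic`` is ``"median"`` (dispersion: scaled MAD) or ``"mean"``
    (dispersion: SD).  When ``predictions`` is given — a frame with
    ``subject_id`` and one column per parameter of predicted values — a
    second set of summaries with ``source == "predicted"`` is emitted.
    Empty strata are omitted (they produce no row).
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    if by not in table.columns:
        raise ValueError(f"no stratification column {by!r}")

    sources = {"observed": table}
    if predictions is not None:
        merged = table[["subject_id", by]].merge(predictions, on="subject_id", how="inner")
        sources["predicted"] = merged

    rows = []
    for source, frame in sources.items():
        for level, group in frame.groupby(by, sort=False, observed=True):
            for param in parameters:
                col = PARAMETER_COLUMNS.get(param, param) if source == "observed" else param
                if col not in group.columns:
                    continue
                values = group[col].dropna().to_numpy(dtype=float)
                if values.size == 0:
                    continue
                if statistic == "median":
                    central = float(np.median(values))
                    dispersion = float(MAD_SCALE * np.median(np.abs(values - central)))
                else:
                    central = float(np.mean(values))
                    dispersion = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
                rows.append(
                    {
                        "variable": by,
                        "level": level,
                        "parameter": param,
                        "statistic": statistic,
                        "central": central,
                        "dispersion": dispersion,
                        "n": int(values.size),
                        "source": source,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "variable", "level", "parameter", "statistic",
            "central", "dispersion", "n", "source",
        ],
    )


def _lookup(summaries: pd.DataFrame, parameter: str, level: str, statistic: str):
    sel = summaries[
        (summaries["parameter"] == parameter)
        & (summaries["level"] == level)
        & (summaries["statistic"] == statistic)
        & (summaries["source"] == "observed")
    ]
    if sel.empty:
        return None
    return float(sel["central"].iloc[0])


def ordering_check(
    status_summaries: pd.DataFrame,
    sex_summaries: Optional[pd.DataFrame] = None,
) -> dict:
    """Evaluate the expected stratum orderings of the derived bioparameters.

    Claims on the weight-status strata: median I_r and I_Xc increase
    underweight → normal → overweight, and the mean phase angle is highest
    for normal weight and lowest for overweight (normal > underweight >
    overweight).  With ``sex_summaries`` supplied, additionally checks that
    the female median exceeds the male median for all three parameters.

    Each claim maps to ``{"status": "pass"|"fail"|"unevaluable",
    "observed": {...}}``.
    """
    report = {}

    def claim(name, values, ok):
        if any(v is None for v in values.values()):
            report[name] = {"status": "unevaluable", "observed": values}
        else:
            report[name] = {"status": "pass" if ok(values) else "fail", "observed": values}

    for param in ("I_r", "I_Xc"):
        vals = {
            lvl: _lookup(status_summaries, param, lvl, "median")
            for lvl in ("underweight", "normal", "overweight")
        }
        claim(
            f"{param}_increases_with_status",
            vals,
            lambda v: v["underweight"] < v["normal"] < v["overweight"],
        )

    vals = {
        lvl: _lookup(status_summaries, "theta", lvl, "mean")
        for lvl in ("underweight", "normal", "overweight")
    }
    claim(
        "theta_normal_highest_overweight_lowest",
        vals,
        lambda v: v["normal"] > v["underweight"] > v["overweight"],
    )

    if sex_summaries is not None:
        for param in ("I_r", "I_Xc", "theta"):
            vals = {s: _lookup(sex_summaries, param, s, "median") for s in ("female", "male")}
            claim(
                f"{param}_female_exceeds_male",
                vals,
                lambda v: v["female"] > v["male"],
            )
    return report


@dataclass(frozen=True)
class TrendLine:
    """Least-squares line of one bioparameter on another within a group."""

    group: str
    response: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: Optional[str] = None  # "vertical" when the predictor is constant


def fit_group_trends(
    table: pd.DataFrame,
    grouping: Optional[Iterable[str]] = None,
    x: str = "I_r",
    y: str = "I_Xc",
    min_points: int = 3,
) -> tuple[list[TrendLine], list[str]]:
    """Per-group least-squares lines in both orientations (y~x and x~y).

    The default grouping is sex × (underweight vs not), the reading under
    which the cohort's index scatter organizes into four straight bands.
    Groups with fewer than ``min_points`` subjects are skipped with a notice.
    A constant predictor yields a line flagged ``degenerate="vertical"``.
    """
    work = table.copy()
    if grouping is None:
        work["_status2"] = np.where(
            work["weight_status"] == "underweight", "underweight", "not-underweight"
        )
        grouping = ["sex", "_status2"]
    else:
        grouping = list(grouping)

    lines: list[TrendLine] = []
    notices: list[str] = []
    for key, group in work.groupby(grouping, sort=True, observed=True):
        label = ":".join(map(str, key if isinstance(key, tuple) else (key,)))
        sub = group[[x, y]].dropna()
        if len(sub) < min_points:
            notices.append(f"group {label}: only {len(sub)} point(s), skipped")
            continue
        for resp, pred in ((y, x), (x, y)):
            px = sub[pred].to_numpy(dtype=float)
            py = sub[resp].to_numpy(dtype=float)
            if np.ptp(px) == 0.0:
                lines.append(
                    TrendLine(label, resp, pred, np.nan, np.nan, np.nan, len(sub), "vertical")
                )
                continue
            fit = sps.linregress(px, py)
            lines.append(
                TrendLine(
                    label, resp, pred,
                    float(fit.slope), float(fit.intercept),
                    float(fit.rvalue**2), len(sub),
                )
            )
    return lines, notices


def trend_table(lines: Iterable[TrendLine]) -> pd.DataFrame:
    """Flatten trend lines for CSV export."""
    return pd.DataFrame(
        [
            {
                "group": t.group,
                "response": t.response,
                "predictor": t.predictor,
                "slope": t.slope,
                "intercept": t.intercept,
                "r_squared": t.r_squared,
                "n": t.n,
                "degenerate": t.degenerate or "",
            }
            for t in lines
        ]
    )


def predicted_vs_true_table(
    observed, predicted, subject_ids: Optional[Iterable] = None
) -> pd.DataFrame:
    """Per-subject observed/predicted pairs with identity-line residuals."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    ids = list(subject_ids) if subject_ids is not None else list(range(obs.size))
    if len(ids) != obs.size:
        raise ValueError("subject_ids length differs from data")
    return pd.DataFrame(
        {
            "subject_id": ids,
            "observed": obs,
            "predicted": pred,
            "residual": pred - obs,
        }
    )
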