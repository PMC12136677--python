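"""Linear support-vector regression of the derived bioparameters.

Each response (specific resistance index ``I_r``, specific reactance index
``I_Xc``, phase angle ``theta``) is predicted from the eleven base subject
features plus the other two derived bioparameters — thirteen features per
model.  Models are linear-kernel epsilon-insensitive SVRs fit on standardized
features; by default the box constraint is 1.0 and epsilon is
``IQR(response)/13.49``, mirroring common regression-toolbox defaults.

Evaluation metrics follow the usual definitions: R² about the observed mean,
MSE, RMSE = sqrt(MSE) and MAE.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "BASE_FEATURES",
    "RESPONSE_COLUMNS",
    "FeatureSpec",
    "MetricsReport",
    "Hyperparameters",
    "RegressionResult",
    "default_feature_spec",
    "compute_metrics",
    "split_cohort",
    "train_linear_svr",
    "model_comparison",
]

#: The eleven base features shared by every response model, as columns of a
#: derived cohort table.
BASE_FEATURES = [
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "weight_status",
    "Z_ohm",
    "Xcc_ohm",
    "ECM_kg",
    "tbw_kotler_L",
    "ICW_L",
    "ECW_L",
]

#: Response name -> column of the derived table.  The phase angle modelled is
#: the dataset-convention one (computed from Xcc), the convention in which the
#: cohort's stratified phase statistics are quoted.
RESPONSE_COLUMNS = {
    "I_r": "I_r",
    "I_Xc": "I_Xc",
    "theta": "theta_dataset_deg",
}

_COMPANIONS = {
    "I_r": ["I_Xc", "theta"],
    "I_Xc": ["I_r", "theta"],
    "theta": ["I_r", "I_Xc"],
}

_SEX_CODE = {"female": 1.0, "male": 0.0}
_STATUS_CODE = {"underweight": -1.0, "normal": 0.0, "overweight": 1.0}


@dataclass(frozen=True)
class FeatureSpec:
    """Response plus the ordered 13-feature set predicting it."""

    response: str
    feature_names: tuple[str, ...]
    status_encoding: str = "onehot"  # or "ordinal"

    def __post_init__(self):
        if self.response not in RESPONSE_COLUMNS:
            raise ValueError(f"unknown response {self.response!r}")
        if self.response in self.feature_names:
            raise ValueError("response must not appear among its own features")


def default_feature_spec(response: str, status_encoding: str = "onehot") -> FeatureSpec:
    """The 13-feature specification for one response: 11 base + 2 companions."""
    if response not in _COMPANIONS:
        raise ValueError(f"unknown response {response!r}")
    return FeatureSpec(
        response=response,
        feature_names=tuple(BASE_FEATURES + _COMPANIONS[response]),
        status_encoding=status_encoding,
    )


@dataclass(frozen=True)
class MetricsReport:
    """Regression accuracy metrics; ``r_squared`` is NaN when the observed
    vector has zero variance (flagged by ``r_squared_defined``)."""

    r_squared: float
    mse: float
    rmse: float
    mae: float
    n: int
    r_squared_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "R2": self.r_squared,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "MAE": self.mae,
            "n": self.n,
        }


def compute_metrics(observed, predicted) -> MetricsReport:
    """R², MSE, RMSE and MAE of predictions against observations."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d vectors")
    if y.size == 0:
        raise ValueError("empty vectors")
    resid = y - yhat
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        defined = True
    else:
        r2, defined = float("nan"), False
    return MetricsReport(r2, mse, rmse, mae, int(y.size), defined)


def split_cohort(
    table: pd.DataFrame,
    train_fraction: float = 0.95,
    seed: int = 0,
    stratify_by: Optional[str] = "weight_status",
) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible train/holdout split, stratified by weight status.

    The training size is the nearest integer to ``train_fraction · n``; the
    remainder forms the holdout.  Cohorts smaller than 20 make a 5% holdout
    degenerate and raise.
    """
    n = len(table)
    if n < 20:
        raise ValueError(f"cohort of {n} subjects is too small for a {train_fraction:.0%} split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    strat = None
    if stratify_by is not None and stratify_by in table.columns:
        labels = table[stratify_by]
        counts = labels.value_counts()
        if counts.min() >= 2 and len(counts) <= (n - n_train):
            strat = labels
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=n_train, random_state=seed, stratify=strat
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass(frozen=True)
class Hyperparameters:
    """Linear-SVR settings; epsilon ``None`` means IQR(response)/13.49."""

    box_constraint: float = 1.0
    epsilon: Optional[float] = None


@dataclass
class RegressionResult:
    feature_spec: FeatureSpec
    coefficients: pd.Series       # in original feature units
    intercept: float
    hyperparameters: Hyperparameters
    epsilon_used: float
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    train_metrics: MetricsReport
    test_metrics: MetricsReport
    cv_metrics: Optional[MetricsReport] = None
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_dropped: int = 0
    notes: list = field(default_factory=list)


def design_matrix(table: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Numeric design matrix for a feature spec (categoricals encoded)."""
    cols = {}
    for name in spec.feature_names:
        if name == "sex":
            cols["sex"] = table["sex"].map(_SEX_CODE).astype(float)
        elif name == "weight_status":
            if spec.status_encoding == "ordinal":
                cols["weight_status"] = table["weight_status"].map(_STATUS_CODE).astype(float)
            else:
                for level in ("underweight", "overweight"):  # normal is reference
                    cols[f"weight_status_{level}"] = (
                        (table["weight_status"] == level).astype(float)
                    )
        else:
            source = RESPONSE_COLUMNS.get(name, name)
            cols[name] = table[source].astype(float)
    return pd.DataFrame(cols, index=table.index)


def _iqr_epsilon(y: np.ndarray) -> float:
    q75, q25 = np.percentile(y, [75, 25])
    eps = (q75 - q25) / 13.49
    return float(eps) if eps > 0 else 1e-6


def train_linear_svr(
    table: pd.DataFrame,
    spec: FeatureSpec,
    hyperparameters: Optional[Hyperparameters] = None,
    seed: int = 0,
    cv_folds: Optional[int] = None,
    train_fraction: float = 0.95,
) -> RegressionResult:
    """Fit a linear-kernel SVR for one response on a 95/5 stratified split.

    Rows with non-finite features or response are dropped listwise and
    counted.  Constant features are retained with a note (standardization
    leaves them inert).  Coefficients are reported in original feature units.
    """
    hp = hyperparameters or Hyperparameters()
    X = design_matrix(table, spec)
    y = table[RESPONSE_COLUMNS[spec.response]].astype(float)
    finite = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(y.to_numpy())
    n_dropped = int((~finite).sum())
    sub = table.loc[finite].reset_index(drop=True)
    X = X.loc[finite].reset_index(drop=True)
    y = y.loc[finite].reset_index(drop=True)

    notes = []
    const = X.columns[X.nunique() <= 1]
    if len(const):
        notes.append(f"constant feature(s) retained: {', '.join(const)}")

    train_idx, test_idx = split_cohort(sub, train_fraction=train_fraction, seed=seed)
    y_train = y.iloc[train_idx].to_numpy()
    eps = hp.epsilon if hp.epsilon is not None else _iqr_epsilon(y_train)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svr", SVR(kernel="linear", C=hp.box_constraint, epsilon=eps)),
        ]
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model.fit(X.iloc[train_idx], y_train)

    pred_train = model.predict(X.iloc[train_idx])
    pred_test = model.predict(X.iloc[test_idx])
    train_metrics = compute_metrics(y_train, pred_train)
    test_metrics = compute_metrics(y.iloc[test_idx].to_numpy(), pred_test)

    cv_metrics = None
    if cv_folds:
        obs_all, pred_all = [], []
        for tr, va in KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(train_idx):
            rows_tr = train_idx[tr]
            rows_va = train_idx[va]
            fold = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svr", SVR(kernel="linear", C=hp.box_constraint, epsilon=eps)),
                ]
            )
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fold.fit(X.iloc[rows_tr], y.iloc[rows_tr].to_numpy())
            obs_all.append(y.iloc[rows_va].to_numpy())
            pred_all.append(fold.predict(X.iloc[rows_va]))
        cv_metrics = compute_metrics(np.concatenate(obs_all), np.concatenate(pred_all))

    scaler: StandardScaler = model.named_steps["scale"]
    svr: SVR = model.named_steps["svr"]
    w_std = svr.coef_.ravel()
    w_orig = w_std / scaler.scale_
    intercept = float(svr.intercept_[0] - np.sum(w_std * scaler.mean_ / scaler.scale_))
    coefficients = pd.Series(w_orig, index=X.columns, name="coefficient")

    role = np.empty(len(sub), dtype=object)
    role[train_idx] = "train"
    role[test_idx] = "test"
    predictions = pd.DataFrame(
        {
            "subject_id": sub["subject_id"],
            "observed": y,
            "predicted": model.predict(X),
            "role": role,
        }
    )
    return RegressionResult(
        feature_spec=spec,
        coefficients=coefficients,
        intercept=intercept,
        hyperparameters=hp,
        epsilon_used=float(eps),
        train_indices=train_idx,
        test_indices=test_idx,
        seed=seed,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        cv_metrics=cv_metrics,
        predictions=predictions,
        n_dropped=n_dropped,
        notes=notes,
    )


@dataclass
class ComparisonEntry:
    name: str
    rank: Optional[int]
    failed: bool
    test_metrics: Optional[MetricsReport]
    error: Optional[str] = None


def _default_candidates() -> list[tuple[str, Callable]]:
    return [
        ("ols", lambda eps: Pipeline([("scale", StandardScaler()), ("ols", LinearRegression())])),
        (
            "linear_svr",
            lambda eps: Pipeline(
                [("scale", StandardScaler()), ("svr", SVR(kernel="linear", C=1.0, epsilon=eps))]
            ),
        ),
    ]


def model_comparison(
    table: pd.DataFrame,
    spec: FeatureSpec,
    candidates: Optional[Sequence[tuple[str, Callable]]] = None,
    seed: int = 0,
    train_fraction: float = 0.95,
) -> list[ComparisonEntry]:
    """Train candidate models on one shared split and rank by holdout RMSE.

    Candidates are ``(name, factory)`` pairs where ``factory(epsilon)``
    returns an unfitted sklearn regressor.  Ties break by MAE, then by
    declaration order.  A candidate that raises is recorded as failed and the
    ranking proceeds without it.
    """
    cand = list(candidates) if candidates is not None else _default_candidates()
    if not cand:
        raise ValueError("candidate set must be nonempty")
    X = design_matrix(table, spec)
    y = table[RESPONSE_COLUMNS[spec.response]].astype(float)
    finite = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(y.to_numpy())
    sub = table.loc[finite].reset_index(drop=True)
    X = X.loc[finite].reset_index(drop=True)
    y = y.loc[finite].reset_index(drop=True)
    train_idx, test_idx = split_cohort(sub, train_fraction=train_fraction, seed=seed)
    eps = _iqr_epsilon(y.iloc[train_idx].to_numpy())

    fitted = []
    for order, (name, factory) in enumerate(cand):
        try:
            model = factory(eps)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                model.fit(X.iloc[train_idx], y.iloc[train_idx].to_numpy())
            metrics = compute_metrics(
                y.iloc[test_idx].to_numpy(), model.predict(X.iloc[test_idx])
            )
            fitted.append((metrics.rmse, metrics.mae, order, name, metrics, None))
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            fitted.append((np.inf, np.inf, order, name, None, str(exc)))

    ranked = sorted(fitted, key=lambda t: (t[0], t[1], t[2]))
    out = []
    rank = 0
    for rmse, _mae, _order, name, metrics, error in ranked:
        failed = metrics is None
        if not failed:
            rank += 1
        out.append(
            ComparisonEntry(
                name=name,
                rank=None if failed else rank,
                failed=failed,
                test_metrics=metrics,
                error=error,
            )
        )
    return out
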