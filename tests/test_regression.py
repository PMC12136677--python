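"""Metrics, splitting, linear-SVR training and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from biaindex import (
    compute_metrics,
    default_feature_spec,
    model_comparison,
    split_cohort,
    train_linear_svr,
)
from biaindex.regression import FeatureSpec, Hyperparameters, design_matrix


# --- compute_metrics -------------------------------------------------------

def test_metrics_hand_example():
    """y=[1,2,3], ŷ=[1,2,4]: MSE=MAE=1/3, RMSE=√(1/3), R²=0.5."""
    m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    assert m.mse == pytest.approx(1 / 3, rel=1e-15)
    assert m.mae == pytest.approx(1 / 3, rel=1e-15)
    assert m.rmse == pytest.approx(np.sqrt(1 / 3), rel=1e-15)
    assert m.r_squared == pytest.approx(0.5, rel=1e-15)
    assert m.n == 3


def test_metrics_perfect_and_null_prediction():
    y = np.array([2.0, 4.0, 9.0, -1.0])
    perfect = compute_metrics(y, y)
    assert perfect.r_squared == 1.0 and perfect.mse == 0.0 and perfect.mae == 0.0
    null = compute_metrics(y, np.full_like(y, y.mean()))
    assert null.r_squared == pytest.approx(0.0, abs=1e-15)


def test_metrics_zero_variance_flagged():
    m = compute_metrics([3.0, 3.0, 3.0], [2.0, 3.0, 4.0])
    assert not m.r_squared_defined
    assert np.isnan(m.r_squared)
    assert m.mse == pytest.approx(2 / 3)


@settings(max_examples=200, derandomize=True)
@given(
    y=hnp.arrays(float, st.integers(2, 50), elements=st.floats(-100, 100)),
    noise=hnp.arrays(float, st.integers(2, 50), elements=st.floats(-10, 10)),
)
def test_metrics_match_sklearn_oracle(y, noise):
    n = min(len(y), len(noise))
    y, yhat = y[:n], y[:n] + noise[:n]
    m = compute_metrics(y, yhat)
    assert m.mse == pytest.approx(mean_squared_error(y, yhat), rel=1e-12, abs=1e-12)
    assert m.mae == pytest.approx(mean_absolute_error(y, yhat), rel=1e-12, abs=1e-12)
    assert m.rmse == pytest.approx(np.sqrt(m.mse), rel=1e-12, abs=1e-12)
    assert m.mae <= m.rmse + 1e-12
    if np.sum((y - y.mean()) ** 2) > 1e-9:
        assert m.r_squared == pytest.approx(r2_score(y, yhat), rel=1e-9, abs=1e-9)
        assert m.r_squared <= 1.0


# --- split_cohort ----------------------------------------------------------

def test_split_sizes_and_partition(derived):
    train, test = split_cohort(derived.table, seed=0)
    assert len(train) == 269 and len(test) == 14  # round(0.95·283) = 269
    union = np.union1d(train, test)
    assert np.array_equal(union, np.arange(len(derived.table)))
    assert len(np.intersect1d(train, test)) == 0


def test_split_reproducible(derived):
    a = split_cohort(derived.table, seed=5)
    b = split_cohort(derived.table, seed=5)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = split_cohort(derived.table, seed=6)
    assert not np.array_equal(a[1], c[1])


def test_split_rejects_tiny_cohort(derived):
    with pytest.raises(ValueError, match="too small"):
        split_cohort(derived.table.head(10))


# --- feature specification -------------------------------------------------

@pytest.mark.parametrize("response", ["I_r", "I_Xc", "theta"])
def test_feature_spec_thirteen_features(response):
    spec = default_feature_spec(response)
    assert len(spec.feature_names) == 13
    assert response not in spec.feature_names


def test_feature_spec_rejects_response_leak():
    with pytest.raises(ValueError, match="own features"):
        FeatureSpec(response="I_Xc", feature_names=("sex", "I_Xc"))


# --- training --------------------------------------------------------------

def test_exact_linear_recovery(derived):
    """A noise-free linear response is recovered near-perfectly when the
    epsilon tube is closed (ε=0) and the box constraint does not bind."""
    lin = derived.table.copy()
    lin["theta_dataset_deg"] = 2.0 * lin["height_cm"] + 1.0
    res = train_linear_svr(
        lin,
        default_feature_spec("theta"),
        hyperparameters=Hyperparameters(box_constraint=10.0, epsilon=0.0),
        seed=0,
    )
    assert res.test_metrics.r_squared >= 0.999
    assert res.train_metrics.r_squared >= 0.999


def test_default_epsilon_is_iqr_scaled(derived):
    res = train_linear_svr(derived.table, default_feature_spec("theta"), seed=0)
    y = res.predictions.query("role == 'train'")["observed"].to_numpy()
    q75, q25 = np.percentile(y, [75, 25])
    assert res.epsilon_used == pytest.approx((q75 - q25) / 13.49, rel=1e-12)


def test_training_invariant_to_feature_order(derived):
    spec = default_feature_spec("theta")
    shuffled = FeatureSpec(
        response="theta",
        feature_names=tuple(reversed(spec.feature_names)),
        status_encoding=spec.status_encoding,
    )
    a = train_linear_svr(derived.table, spec, seed=1)
    b = train_linear_svr(derived.table, shuffled, seed=1)
    np.testing.assert_allclose(
        a.predictions["predicted"], b.predictions["predicted"], atol=1e-8
    )


def test_predictions_invariant_to_feature_rescaling(derived):
    """Standardization makes an affine rescale of any feature a no-op."""
    scaled = derived.table.copy()
    scaled["height_cm"] = scaled["height_cm"] * 12.7 + 3.0
    a = train_linear_svr(derived.table, default_feature_spec("theta"), seed=2)
    b = train_linear_svr(scaled, default_feature_spec("theta"), seed=2)
    np.testing.assert_allclose(
        a.predictions["predicted"], b.predictions["predicted"], rtol=1e-6, atol=1e-6
    )


def test_coefficients_reproduce_pipeline_predictions(derived):
    res = train_linear_svr(derived.table, default_feature_spec("I_Xc"), seed=0)
    X = design_matrix(derived.table, res.feature_spec)
    manual = X.to_numpy() @ res.coefficients.to_numpy() + res.intercept
    np.testing.assert_allclose(manual, res.predictions["predicted"], rtol=1e-8, atol=1e-8)


def test_listwise_deletion_of_nonfinite_rows(derived):
    broken = derived.table.copy()
    broken.loc[broken.index[:3], "ECM_kg"] = np.nan
    res = train_linear_svr(broken, default_feature_spec("theta"), seed=0)
    assert res.n_dropped == 3
    assert len(res.predictions) == len(broken) - 3


def test_constant_feature_noted_not_dropped(derived):
    frozen = derived.table.copy()
    frozen["ECM_kg"] = 11.0
    res = train_linear_svr(frozen, default_feature_spec("theta"), seed=0)
    assert any("constant" in note for note in res.notes)
    assert "ECM_kg" in res.coefficients.index


def test_cross_validated_metrics_available(derived):
    res = train_linear_svr(derived.table, default_feature_spec("theta"), seed=0, cv_folds=5)
    assert res.cv_metrics is not None
    assert res.cv_metrics.n == len(res.train_indices)
    assert res.cv_metrics.r_squared > 0.9


# --- model comparison ------------------------------------------------------

def test_single_candidate_ranks_first(derived):
    entries = model_comparison(
        derived.table,
        default_feature_spec("theta"),
        candidates=[("only", lambda eps: __import__("sklearn.dummy", fromlist=["DummyRegressor"]).DummyRegressor())],
    )
    assert entries[0].name == "only" and entries[0].rank == 1


def test_identical_candidates_tie_break_by_declaration_order(derived):
    from sklearn.linear_model import LinearRegression
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    factory = lambda eps: Pipeline([("s", StandardScaler()), ("m", LinearRegression())])
    entries = model_comparison(
        derived.table,
        default_feature_spec("theta"),
        candidates=[("first", factory), ("second", factory)],
    )
    assert [e.name for e in entries] == ["first", "second"]
    assert [e.rank for e in entries] == [1, 2]


def test_failing_candidate_recorded_not_fatal(derived):
    def broken(eps):
        raise RuntimeError("cannot build")

    entries = model_comparison(
        derived.table,
        default_feature_spec("theta"),
        candidates=[("bad", broken)] + [
            ("ols", lambda eps: __import__("sklearn.linear_model", fromlist=["LinearRegression"]).LinearRegression())
        ],
    )
    by_name = {e.name: e for e in entries}
    assert by_name["bad"].failed and by_name["bad"].rank is None
    assert by_name["ols"].rank == 1


def test_epsilon_insensitive_at_least_matches_ols_under_heavy_tails(default_config):
    """With t(2) response noise the robust loss wins the RMSE ranking in the
    median over 20 seeded replicates."""
    from biaindex import derive_all, generate_cohort

    wins = 0
    for s in range(20):
        sc = generate_cohort(default_config.model_copy(update={"seed": 200 + s, "n_subjects": 300}))
        d = derive_all(sc.table).table
        rng = np.random.default_rng(100 + s)
        d["theta_dataset_deg"] = 0.05 * d["height_cm"] + rng.standard_t(2, len(d))
        entries = model_comparison(d, default_feature_spec("theta"), seed=s)
        ranks = {e.name: e.rank for e in entries}
        wins += ranks["linear_svr"] <= ranks["ols"]
    assert wins >= 10
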