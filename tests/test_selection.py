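import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifecourse import (
    CovTestResult,
    covariance_test,
    drop_collinear,
    kkt_violation,
    lars_path,
    residualize,
    select_model,
)
from lifecourse.errors import DegenerateOutcomeError, RankDeficiencyError


def correlated_instance(seed, n=50, p=6, rho=0.5):
    rng = np.random.default_rng(seed)
    cov = rho * np.ones((p, p)) + (1 - rho) * np.eye(p)
    X = rng.normal(size=(n, p)) @ np.linalg.cholesky(cov).T
    beta = np.zeros(p)
    beta[0], beta[2] = 1.0, -0.5
    y = X @ beta + rng.normal(size=n)
    return X, y


# --- residualization -------------------------------------------------------

def test_residualize_removes_confounder_signal(rng):
    n = 200
    c = rng.normal(size=(n, 2))
    x = 2.0 + c @ np.array([1.5, -0.7]) + rng.normal(size=n)
    X = pd.DataFrame({"x": x, "copy_of_c": c[:, 0]})
    R = residualize(X, pd.DataFrame(c, columns=["c1", "c2"]))
    assert np.allclose(R["copy_of_c"], 0.0, atol=1e-10)
    for col in R.columns:
        assert abs(R[col].mean()) < 1e-10
        assert abs(np.corrcoef(R["x"], c[:, 0])[0, 1]) < 1e-8


def test_residualize_without_confounders_centers(rng):
    X = pd.DataFrame({"x": rng.normal(3.0, 1.0, 50)})
    R = residualize(X)
    assert np.allclose(R["x"], X["x"] - X["x"].mean())


def test_residualize_rank_deficiency_names_aliased(rng):
    n = 60
    c1 = rng.normal(size=n)
    C = pd.DataFrame({"c1": c1, "c2": 2 * c1})
    with pytest.raises(RankDeficiencyError, match="c2"):
        residualize(pd.DataFrame({"x": rng.normal(size=n)}), C)


# --- collinearity screen ---------------------------------------------------

def test_drop_collinear_removes_duplicate(rng):
    x = rng.normal(size=100)
    X = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.normal(size=100),
                      "c": rng.normal(size=100)})
    reduced, log = drop_collinear(X, threshold=0.9)
    assert list(reduced.columns) == ["a", "c"]
    assert log[0]["kept"] == "a" and log[0]["dropped"] == "b"
    assert abs(log[0]["r"]) > 0.9


def test_drop_collinear_prefers_sensitive_period_names(rng):
    x = rng.normal(size=100)
    X = pd.DataFrame({"derived": x + 1e-6 * rng.normal(size=100), "sp_x": x})
    reduced, log = drop_collinear(X, threshold=0.9)
    assert list(reduced.columns) == ["sp_x"]
    assert log[0]["kept"] == "sp_x"


def test_drop_collinear_keeps_independent_columns(rng):
    X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
    reduced, log = drop_collinear(X)
    assert list(reduced.columns) == list("abcd")
    assert log == []


# --- LARS / lasso path -----------------------------------------------------

def test_single_column_r2_is_squared_correlation(rng):
    x = rng.normal(size=80)
    y = 0.5 * x + rng.normal(size=80)
    path = lars_path(pd.DataFrame({"x": x}), y)
    assert path.r2_per_step[-1] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)


def test_entry_order_orthogonal_design(rng):
    n, p = 120, 5
    Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    X = Q * np.sqrt(n - 1)
    y = X @ np.array([0.9, -0.1, 0.5, 0.0, -0.3]) + 0.01 * rng.normal(size=n)
    path = lars_path(X, y, standardize=False)
    order = np.argsort(-np.abs(X.T @ (y - y.mean())))
    # entry order of an orthogonal design follows descending |x^T y|
    entered = [path.columns.index(v) for v in path.entry_order]
    assert entered == list(order)


@pytest.mark.parametrize("seed", [0, 1, 7, 42])
def test_path_matches_independent_lars_oracle(seed):
    from sklearn.linear_model import lars_path as sk_lars

    X, y = correlated_instance(seed)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    yc = y - y.mean()
    path = lars_path(Xs, yc, standardize=False)
    alphas, _, coefs = sk_lars(Xs, yc, method="lasso")
    assert len(path.knots) == len(alphas)
    assert np.allclose(path.knots, alphas * len(y), atol=1e-9)
    assert np.allclose(path.coefs, coefs.T, atol=1e-9)


@pytest.mark.parametrize("seed", [3, 11])
def test_path_matches_coordinate_descent(seed):
    from sklearn.linear_model import Lasso

    X, y = correlated_instance(seed, n=60)
    path = lars_path(pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])]), y)
    Xs = (X - path.x_mean) / path.x_scale
    yc = y - path.y_mean
    n = len(y)
    lams = list(path.knots[1:-1]) + [
        0.5 * (path.knots[k] + path.knots[k + 1]) for k in range(len(path.knots) - 1)
    ]
    for lam in lams:
        if lam <= 0:
            continue
        cd = Lasso(alpha=lam / n, fit_intercept=False, tol=1e-14, max_iter=200000)
        cd.fit(Xs, yc)
        assert np.allclose(path.coef_at(lam), cd.coef_, atol=1e-6)


def test_kkt_holds_at_every_knot():
    X, y = correlated_instance(5)
    path = lars_path(X, y)
    for k in range(len(path.knots)):
        assert kkt_violation(path, X, y, k) < 1e-8


def test_r2_monotone_and_final_matches_ols():
    X, y = correlated_instance(9)
    path = lars_path(X, y)
    r2 = path.r2_per_step
    assert np.all(np.diff(r2) >= -1e-12)
    Xs = (X - path.x_mean) / path.x_scale
    yc = y - path.y_mean
    bh, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    resid = yc - Xs @ bh
    assert r2[-1] == pytest.approx(1 - resid @ resid / (yc @ yc))


def test_degenerate_inputs_rejected(rng):
    X = rng.normal(size=(30, 3))
    with pytest.raises(DegenerateOutcomeError):
        lars_path(X, np.ones(30))
    Xc = X.copy()
    Xc[:, 1] = 2.0
    with pytest.raises(ValueError, match="constant"):
        lars_path(Xc, rng.normal(size=30))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_path_properties_random_instances(seed):
    X, y = correlated_instance(seed, n=40, p=4)
    path = lars_path(X, y)
    assert np.all(np.diff(path.knots) < 0)          # strictly decreasing knots
    assert path.knots[-1] == 0.0
    for k in range(len(path.knots)):
        assert kkt_violation(path, X, y, k) < 1e-8


# --- covariance test -------------------------------------------------------

def test_covtest_known_sigma_scales_inversely():
    X, y = correlated_instance(2)
    path = lars_path(X, y)
    t1 = covariance_test(path, X, y, sigma2=1.0)
    t2 = covariance_test(path, X, y, sigma2=2.0)
    for a, b in zip(t1.steps, t2.steps):
        assert b["T"] == pytest.approx(a["T"] / 2)


def test_covtest_invariant_to_column_scaling():
    X, y = correlated_instance(4)
    path_a = lars_path(X, y)
    Xb = X * np.array([1.0, 10.0, 0.1, 5.0, 1.0, 2.0])
    path_b = lars_path(Xb, y)
    pa = covariance_test(path_a, X, y).p_values
    pb = covariance_test(path_b, Xb, y).p_values
    assert np.allclose(pa, pb, atol=1e-10)


def test_covtest_estimated_sigma_needs_enough_rows():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 4))
    y = rng.normal(size=5)
    path = lars_path(X, y, standardize=False)
    with pytest.raises(ValueError, match="sigma"):
        covariance_test(path, X, y)
    with pytest.raises(ValueError, match="positive"):
        covariance_test(path, X, y, sigma2=-1.0)


def test_covtest_strong_signal_small_p():
    rng = np.random.default_rng(8)
    n = 200
    X = rng.normal(size=(n, 4))
    y = 2.0 * X[:, 1] + 0.1 * rng.normal(size=n)
    path = lars_path(X, y)
    res = covariance_test(path, X, y)
    assert res.steps[0]["variable"] == "x1"
    assert res.steps[0]["p"] < 1e-6


# --- selection -------------------------------------------------------------

def fake_covtest(path, ps):
    steps = [{"step": i + 1, "variable": v, "lambda": 1.0, "lambda_next": 0.5,
              "T": -np.log(p), "p": p} for i, (v, p) in enumerate(zip(path.entry_order, ps))]
    return CovTestResult(steps=steps, sigma2_hat=1.0)


def test_select_model_supported_prefix():
    X, y = correlated_instance(6)
    path = lars_path(X, y)
    k = len(path.entry_order)
    sel = select_model(path, fake_covtest(path, [0.001, 0.02, 0.5, 0.01][:k]))
    assert sel.first_selected == path.entry_order[0]
    assert sel.supported
    assert sel.n_supported_steps == 2

    sel2 = select_model(path, fake_covtest(path, [0.4, 0.01][: min(2, k)]))
    assert sel2.first_selected == path.entry_order[0]  # carried forward regardless
    assert not sel2.supported
    assert sel2.n_supported_steps == 0


def test_selection_invariant_to_confounder_contamination(rng):
    # adding a linear function of confounders to candidates must not change
    # the entry order after residualization
    n = 300
    C = pd.DataFrame(rng.normal(size=(n, 2)), columns=["age", "parental_osc"])
    X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
    y = 0.8 * X["b"].to_numpy() - 0.4 * X["d"].to_numpy() + rng.normal(size=n)
    Xdirty = X + np.outer(C["age"], np.array([1.0, -2.0, 0.5, 3.0]))
    p_clean = lars_path(residualize(X, C), y)
    p_dirty = lars_path(residualize(Xdirty, C), y)
    assert p_clean.entry_order == p_dirty.entry_order
    assert np.allclose(p_clean.knots, p_dirty.knots, atol=1e-8)
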