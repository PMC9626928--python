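import math

import numpy as np
import pandas as pd
import pytest

from lifecourse import (
    ConfounderSet,
    TrajectoryFit,
    confounder_set_for,
    fdr_adjust,
    fit_baseline,
    fit_binary,
    fit_trajectory,
    jn_boundaries,
    johnson_neyman,
    sex_interaction_test,
    standard_confounder_sets,
)
from lifecourse.errors import SeparationError

from conftest import make_regression_frame


# --- confounder sets -------------------------------------------------------

def test_confounder_sets_are_nested():
    sets = standard_confounder_sets()
    v1, v2, v3 = (set(sets[k].variables) for k in ("model1", "model2", "model3"))
    assert v1 < v2 < v3
    assert v1 == {"age", "parental_osc"}


def test_exposure_to_confounder_mapping():
    assert confounder_set_for("sp_child").label == "model1"
    assert confounder_set_for("sp_child").prior_period_nsd is None
    assert confounder_set_for("sp_young").prior_period_nsd == "sp_child"
    mid = confounder_set_for("sp_midlate")
    assert mid.label == "model3"
    assert mid.prior_period_nsd == "sp_young"
    assert "sp_young" in mid.all_terms
    assert confounder_set_for("accumulation").label == "model3"


# --- baseline OLS ----------------------------------------------------------

def test_baseline_recovers_known_slope():
    df = make_regression_frame(n=4000, b=0.02, noise=0.05, seed=3)
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    effects = fit_baseline(df, "expo", cs)
    expo = effects[0]
    # predictor is scaled to unit sd, so b is 0.02 * sd(x) = 0.04
    true_b = 0.02 * df["expo"].std(ddof=1)
    assert expo.term == "expo"
    assert expo.ci_low < true_b < expo.ci_high
    assert expo.b == pytest.approx(true_b, abs=0.004)
    # standardized beta consistency: beta = b * sd(design col) / sd(y)
    assert expo.beta == pytest.approx(expo.b / df["fi"].std(ddof=1), rel=1e-2)


def test_baseline_binary_confounder_not_rescaled():
    df = make_regression_frame(n=4000, seed=5)
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    eff = {e.term: e for e in fit_baseline(df, "expo", cs)}
    # generated with +0.01 for parental_osc == 1, on the original 0/1 coding
    assert eff["parental_osc"].b == pytest.approx(0.01, abs=0.006)


def test_baseline_too_few_cases():
    df = make_regression_frame(n=12)
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    with pytest.raises(ValueError, match="complete cases"):
        fit_baseline(df, "expo", cs)


# --- trajectory mixed model ------------------------------------------------

def simulate_long(n=250, b_exp=0.02, b_int=0.01, seed=0, slope_sd=0.022):
    rng = np.random.default_rng(seed)
    ages = np.array([70.0, 73.0, 76.0, 79.0, 82.0])
    x = rng.normal(size=n)
    parental = (rng.random(n) < 0.7).astype(int)
    u0 = rng.normal(0, 0.06, n)
    u1 = rng.normal(0, slope_sd, n)
    rows = []
    a_s = (ages - ages.mean()) / ages.std(ddof=1)
    for i in range(n):
        for w, a in enumerate(a_s):
            y = (0.14 + b_exp * x[i] + 0.01 * parental[i] + u0[i]
                 + (0.028 + b_int * x[i] + u1[i]) * a
                 + rng.normal(0, 0.037))
            rows.append((f"p{i}", ages[w], x[i], parental[i], y))
    return pd.DataFrame(rows, columns=["person_id", "age", "expo", "parental_osc", "fi"])


@pytest.fixture(scope="module")
def long_fit():
    df = simulate_long(seed=17)
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    return df, fit_trajectory(df, "expo", cs)


def test_trajectory_recovers_fixed_effects(long_fit):
    df, fit = long_fit
    # truth is expressed per sd of the same five-wave age grid the fit scales by
    k = np.array([70, 73, 76, 79, 82.0]).std(ddof=1) / fit.age_scale
    se_int = math.sqrt(fit.cov_fe[1, 1])
    assert abs(fit.b_int * k - 0.01) < 3 * se_int
    se_exp = math.sqrt(fit.cov_fe[0, 0])
    assert abs(fit.b_exp - 0.02) < 3 * se_exp
    assert fit.converged
    assert fit.n_persons == 250 and fit.n_obs == 1250


def test_trajectory_variance_components(long_fit):
    _, fit = long_fit
    vc = fit.variance_components
    for name in ("intercept", "slope", "residual"):
        assert vc[name]["variance"] >= 0
        assert vc[name]["sd"] == pytest.approx(math.sqrt(vc[name]["variance"]))
    assert 0.03 < vc["intercept"]["sd"] < 0.09
    assert vc["residual"]["sd"] == pytest.approx(0.037, abs=0.008)


def test_trajectory_affine_age_invariance(long_fit):
    df, fit = long_fit
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    df2 = df.copy()
    df2["age"] = 2.0 * df2["age"] + 5.0  # affine rescale -> same standardized age
    fit2 = fit_trajectory(df2, "expo", cs)
    assert fit2.b_exp == pytest.approx(fit.b_exp, abs=1e-6)
    assert fit2.b_int == pytest.approx(fit.b_int, abs=1e-6)


# --- Johnson-Neyman --------------------------------------------------------

def test_jn_boundaries_match_quadratic_roots():
    b_exp, b_int, v_e, v_i, cov, t = 1.0, 1.0, 1.0, 0.04, 0.0, 1.96
    roots = jn_boundaries(b_exp, b_int, v_e, v_i, cov, t)
    A = b_int**2 - t**2 * v_i
    B = 2 * (b_exp * b_int - t**2 * cov)
    C = b_exp**2 - t**2 * v_e
    expected = sorted(np.roots([A, B, C]).real)
    assert len(roots) == 2
    assert np.allclose(roots, expected, atol=1e-10)
    # verify the borderline condition itself at each root
    for a in roots:
        lhs = (b_exp + a * b_int) ** 2
        rhs = t**2 * (v_e + a**2 * v_i + 2 * a * cov)
        assert lhs == pytest.approx(rhs, rel=1e-9)


def test_jn_no_roots_when_never_borderline():
    # overwhelming uncertainty: slope never significant, discriminant < 0
    assert jn_boundaries(0.1, 0.01, 100.0, 100.0, 0.0, 1.96) == []


def constructed_fit(b_exp, b_int, v_e, v_i, cov, lo=-2.0, hi=2.0):
    return TrajectoryFit(
        fixed=[], variance_components={}, converged=True, method="REML",
        exposure="expo", interaction="expo:age", moderator="age",
        b_exp=b_exp, b_int=b_int,
        cov_fe=np.array([[v_e, cov], [cov, v_i]]),
        age_center=76.0, age_scale=4.743,
        observed_moderator=np.linspace(lo, hi, 9),
        n_persons=100, n_obs=500,
    )


def test_jn_regions_and_age_transform():
    fit = constructed_fit(0.5, 0.8, 0.01, 0.02, 0.0)
    res = johnson_neyman(fit, alpha=0.05, fdr=False)
    assert res.t_crit == pytest.approx(1.959964, abs=1e-5)
    # boundaries inside the observed range split it into significant regions
    for b in res.boundaries:
        assert -2.0 < b < 2.0
    for lo, hi in res.regions_age():
        assert lo < hi
    # age transform is affine in the scaled boundaries
    for b, ba in zip(res.boundaries, res.boundaries_age()):
        assert ba == pytest.approx(b * 4.743 + 76.0)


def test_jn_fdr_regions_subset_of_unadjusted():
    fit = constructed_fit(0.5, 0.8, 0.01, 0.02, 0.001)
    plain = johnson_neyman(fit, alpha=0.05, fdr=False)
    adj = johnson_neyman(fit, alpha=0.05, fdr=True)
    assert adj.adjusted_alpha <= plain.alpha
    for lo, hi in adj.regions:
        assert any(plo - 1e-12 <= lo and hi <= phi + 1e-12
                   for plo, phi in plain.regions)


def test_jn_constant_significant_slope_whole_range():
    fit = constructed_fit(1.0, 0.0, 0.01, 0.0, 0.0)
    res = johnson_neyman(fit, alpha=0.05, fdr=False)
    assert res.boundaries == []
    assert res.regions == [(-2.0, 2.0)]


# --- sex interaction -------------------------------------------------------

def sexed_frame(n=1200, b_male=0.03, b_female=0.0, seed=2):
    rng = np.random.default_rng(seed)
    sex = (rng.random(n) < 0.5).astype(int)
    x = rng.normal(size=n)
    age = rng.normal(70, 0.8, n)
    parental = (rng.random(n) < 0.7).astype(int)
    y = 0.14 + np.where(sex == 1, b_male, b_female) * x + rng.normal(0, 0.06, n)
    return pd.DataFrame({"person_id": [f"p{i}" for i in range(n)], "fi": y,
                         "expo": x, "age": age, "parental_osc": parental,
                         "sex": sex})


def test_sex_interaction_detects_differential_effect():
    df = sexed_frame()
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    eff = sex_interaction_test(df, "expo", cs)
    assert eff.term == "sex:expo"
    assert eff.b > 0
    assert eff.p_value < 0.05


def test_sex_interaction_sign_flips_with_coding():
    df = sexed_frame()
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    a = sex_interaction_test(df, "expo", cs)
    df2 = df.assign(sex=1 - df["sex"])
    b = sex_interaction_test(df2, "expo", cs)
    assert b.b == pytest.approx(-a.b, abs=1e-8)
    assert b.p_value == pytest.approx(a.p_value, abs=1e-8)


def test_sex_interaction_requires_both_sexes():
    df = sexed_frame().assign(sex=1)
    cs = ConfounderSet("model1", ("age", "parental_osc"))
    with pytest.raises(ValueError, match="both sexes"):
        sex_interaction_test(df, "expo", cs)


# --- binary outcome --------------------------------------------------------

def test_binary_baseline_recovers_odds_ratio():
    rng = np.random.default_rng(4)
    n = 3000
    x = rng.normal(size=n)
    age = rng.normal(70, 0.8, n)
    logit = -2.0 + 0.85 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    df = pd.DataFrame({"fi": y, "expo": x, "age": age})
    cs = ConfounderSet("model1", ("age",))
    eff = fit_binary(df, "expo", cs, cutpoint=0.5)[0]
    assert eff.term == "expo"
    assert eff.ci_low < math.exp(0.85) < eff.ci_high
    assert 1.9 < eff.b < 2.9
    assert eff.beta is None


def test_binary_too_few_events():
    df = pd.DataFrame({"fi": [0.0] * 50 + [1.0] * 3,
                       "expo": np.arange(53.0), "age": np.arange(53.0)})
    cs = ConfounderSet("model1", ("age",))
    with pytest.raises(ValueError, match="events"):
        fit_binary(df, "expo", cs, cutpoint=0.5)


def test_binary_separation_raises():
    rng = np.random.default_rng(0)
    n = 100
    x = rng.normal(size=n)
    df = pd.DataFrame({"fi": (x > 0).astype(float), "expo": x,
                       "age": rng.normal(70, 1, n)})
    cs = ConfounderSet("model1", ("age",))
    with pytest.raises(SeparationError):
        fit_binary(df, "expo", cs, cutpoint=0.5)


# --- FDR -------------------------------------------------------------------

def test_fdr_adjust_worked_example():
    assert np.allclose(fdr_adjust([0.01, 0.04]), [0.02, 0.04])
    assert np.allclose(fdr_adjust([0.5]), [0.5])
    assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_fdr_adjust_matches_hand_rolled_bh(rng):
    p = rng.random(25)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    assert np.allclose(fdr_adjust(p), adj)


def test_fdr_adjust_rejects_invalid():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        fdr_adjust([0.5, float("nan")])
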