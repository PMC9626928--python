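"""Stage 2: effect estimation for the selected life-course model.

Associations are estimated on two outcomes:

* *baseline frailty* (wave 1, around age 70) by ordinary least squares, and
* *frailty progression* (five waves, ages ~70-82) by a linear mixed-effects
  model with random intercepts and random age slopes per person, where the
  exposure x age interaction captures differences in the rate of frailty
  accumulation.

Continuous predictors are mean-centred and scaled to unit standard deviation,
so coefficients ``b`` are outcome units per 1-sd of predictor; fully
standardized coefficients ``beta`` additionally scale by the outcome sd.
Confounders follow three nested DAG-based adjustment sets, optionally
augmented with the previous period's deprivation to address selection into
similar neighborhoods.  Johnson-Neyman machinery locates the moderator (age)
regions where the conditional exposure slope is significant, with an optional
false-discovery-rate adjustment of the critical value over the observed age
grid.  Sensitivity variants swap the continuous Frailty Index for a
robust/frail dichotomy analysed by (mixed-effects) logistic regression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, ConvergenceWarning

from .errors import ConvergenceError, RankDeficiencyError, SeparationError

__all__ = [
    "ConfounderSet",
    "standard_confounder_sets",
    "confounder_set_for",
    "EffectEstimate",
    "TrajectoryFit",
    "JNResult",
    "fit_baseline",
    "fit_trajectory",
    "johnson_neyman",
    "jn_boundaries",
    "sex_interaction_test",
    "fit_binary",
    "fdr_adjust",
]


# ---------------------------------------------------------------------------
# confounder sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfounderSet:
    """A named, ordered adjustment set; optionally adds the prior period's NSD."""

    label: str
    variables: tuple[str, ...]
    prior_period_nsd: str | None = None

    def with_prior(self, prior: str | None) -> "ConfounderSet":
        return ConfounderSet(self.label, self.variables, prior)

    @property
    def all_terms(self) -> list[str]:
        terms = list(self.variables)
        if self.prior_period_nsd:
            terms.append(self.prior_period_nsd)
        return terms


def standard_confounder_sets(
    age: str = "age",
    parental_osc: str = "parental_osc",
    education: str = "education_years",
    childhood_smoking: str = "childhood_smoking",
    iq: str = "iq_age11",
    adult_osc: str = "adult_osc",
    current_smoking: str = "current_smoking",
) -> dict[str, ConfounderSet]:
    """The three nested DAG-based adjustment sets.

    model1: age + parental occupational social class (common confounders);
    model2: model1 + education, childhood smoking, childhood IQ;
    model3: model2 + adult occupational social class, current smoking.
    """
    m1 = (age, parental_osc)
    m2 = m1 + (education, childhood_smoking, iq)
    m3 = m2 + (adult_osc, current_smoking)
    return {
        "model1": ConfounderSet("model1", m1),
        "model2": ConfounderSet("model2", m2),
        "model3": ConfounderSet("model3", m3),
    }


#: Most appropriate adjustment per exposure (DAG mapping), and the previous
#: period used to address selection into similar neighborhoods.
_EXPOSURE_MODEL = {
    "sp_child": ("model1", None),
    "sp_young": ("model2", "sp_child"),
    "em_early": ("model2", None),
    "sp_midlate": ("model3", "sp_young"),
    "accumulation": ("model3", None),
    "em_late": ("model3", None),
}


def confounder_set_for(exposure: str, sets: dict[str, ConfounderSet] | None = None) -> ConfounderSet:
    """The DAG-appropriate confounder set for a life-course exposure."""
    sets = sets or standard_confounder_sets()
    label, prior = _EXPOSURE_MODEL.get(exposure, ("model3", None))
    return sets[label].with_prior(prior)


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------

def _is_binary(col: pd.Series) -> bool:
    vals = set(pd.unique(col.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def _prepare(data: pd.DataFrame, terms: list[str], outcome: str):
    """Complete-case design with continuous terms mean-centred and sd-scaled.

    Returns (design DataFrame with intercept, outcome Series, per-term sd of
    the design column as entered, outcome sd, scaling info dict).
    """
    cols = [outcome] + terms
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    df = data[cols].dropna().copy()
    scaling = {}
    for t in terms:
        s = pd.to_numeric(df[t])
        if _is_binary(s):
            df[t] = s.astype(float)
            scaling[t] = {"center": 0.0, "scale": 1.0, "binary": True}
        else:
            mu, sd = float(s.mean()), float(s.std(ddof=1))
            if sd == 0:
                raise RankDeficiencyError(f"term {t!r} is constant", [t])
            df[t] = (s - mu) / sd
            scaling[t] = {"center": mu, "scale": sd, "binary": False}
    X = sm.add_constant(df[terms], has_constant="add")
    y = pd.to_numeric(df[outcome]).astype(float)
    sds = {t: float(df[t].std(ddof=1)) for t in terms}
    return df, X, y, sds, scaling


def _check_rank(X: pd.DataFrame):
    r = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if r < X.shape[1]:
        aliased = []
        prev = 0
        M = X.to_numpy(dtype=float)
        for k in range(M.shape[1]):
            rk = np.linalg.matrix_rank(M[:, : k + 1])
            if rk == prev:
                aliased.append(X.columns[k])
            prev = rk
        raise RankDeficiencyError(f"design is rank deficient; aliased terms: {aliased}", aliased)


@dataclass(frozen=True)
class EffectEstimate:
    """One regression term: coefficient, Wald 95% CI, p-value, standardized beta."""

    term: str
    b: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float | None = None

    def to_dict(self) -> dict:
        return {"term": self.term, "b": self.b, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p_value": self.p_value, "beta": self.beta}


def _effects_from_fit(params, bse, pvals, conf, terms, sds, sd_y) -> list[EffectEstimate]:
    out = []
    for t in terms:
        out.append(EffectEstimate(
            term=t, b=float(params[t]),
            ci_low=float(conf.loc[t, 0]), ci_high=float(conf.loc[t, 1]),
            p_value=float(pvals[t]),
            beta=float(params[t]) * sds.get(t, 1.0) / sd_y if sd_y > 0 else math.nan,
        ))
    return out


# ---------------------------------------------------------------------------
# baseline (wave 1) linear regression
# ---------------------------------------------------------------------------

def fit_baseline(
    data: pd.DataFrame,
    exposure: str,
    confounders: ConfounderSet,
    outcome: str = "fi",
) -> list[EffectEstimate]:
    """OLS of baseline frailty on one exposure plus a confounder set.

    Requires at least ``10 + number of terms`` complete cases.  ``b`` is in
    outcome units per 1-sd of a continuous predictor (binary predictors stay
    0/1); ``beta`` additionally scales by the outcome sd.
    """
    terms = [exposure] + confounders.all_terms
    df, X, y, sds, _ = _prepare(data, terms, outcome)
    if len(df) < 10 + len(terms):
        raise ValueError(f"too few complete cases ({len(df)}) for {len(terms)} terms")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    conf = res.conf_int()
    return _effects_from_fit(res.params, res.bse, res.pvalues, conf, terms,
                             sds, float(y.std(ddof=1)))


# ---------------------------------------------------------------------------
# trajectory (mixed-effects) regression
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    """Linear mixed model of frailty progression with random intercepts and slopes."""

    fixed: list[EffectEstimate]
    variance_components: dict          # name -> {"variance": v, "sd": sqrt(v)}
    converged: bool
    method: str
    exposure: str
    interaction: str
    moderator: str
    b_exp: float
    b_int: float
    cov_fe: np.ndarray                 # 2x2 covariance of (b_exp, b_int)
    age_center: float
    age_scale: float
    observed_moderator: np.ndarray     # scaled-age values present in the data
    n_persons: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "fixed": [e.to_dict() for e in self.fixed],
            "variance_components": self.variance_components,
            "converged": self.converged,
            "method": self.method,
            "n_persons": self.n_persons,
            "n_obs": self.n_obs,
        }


def fit_trajectory(
    long_data: pd.DataFrame,
    exposure: str,
    confounders: ConfounderSet,
    outcome: str = "fi",
    age: str = "age",
    person: str = "person_id",
) -> TrajectoryFit:
    """REML mixed model: FI ~ exposure * age + confounders + (1 + age | person).

    Age is mean-centred and scaled to unit sd, so the exposure x age
    interaction is the change in frailty per 1-sd exposure per 1-sd of age —
    the frailty-progression effect.  Variance components are reported as
    (variance, sd) for the random intercept, the random age slope and the
    residual; a variance estimated at the boundary (0) yields a warning, not
    an error.
    """
    terms = [exposure, age] + [c for c in confounders.all_terms if c != age]
    cols = list(dict.fromkeys([person] + terms + [outcome]))
    df = long_data[cols].dropna().copy()
    inter = f"{exposure}:{age}"

    scaling = {}
    for t in terms:
        s = pd.to_numeric(df[t])
        if _is_binary(s):
            df[t] = s.astype(float)
        else:
            mu, sd = float(s.mean()), float(s.std(ddof=1))
            df[t] = (s - mu) / sd
            scaling[t] = (mu, sd)
    df[inter] = df[exposure] * df[age]

    fe_terms = [exposure, age] + [c for c in confounders.all_terms if c != age] + [inter]
    X = sm.add_constant(df[fe_terms], has_constant="add")
    _check_rank(X)
    y = pd.to_numeric(df[outcome]).astype(float)

    waves_per_person = df.groupby(person).size()
    if (waves_per_person >= 2).mean() < 0.5:
        warnings.warn("fewer than half of persons contribute 2+ waves; "
                      "slope variance is weakly identified", stacklevel=2)

    model = sm.MixedLM(y, X, groups=df[person],
                       exog_re=sm.add_constant(df[[age]], has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=True, method=["lbfgs", "bfgs", "cg", "powell"])
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"mixed model failed: {exc}") from exc
    if not res.converged or not np.all(np.isfinite(res.params)):
        raise ConvergenceError(
            "mixed model did not converge "
            f"(optimizer trace: converged={res.converged}, "
            f"params finite={bool(np.all(np.isfinite(res.params)))})")

    cov_re = np.asarray(res.cov_re)
    v_int_re, v_slope_re = float(cov_re[0, 0]), float(cov_re[1, 1])
    v_resid = float(res.scale)
    if min(v_int_re, v_slope_re) <= 1e-10:
        warnings.warn("a random-effect variance was estimated at the boundary (0)",
                      stacklevel=2)
    vc = {
        "intercept": {"variance": v_int_re, "sd": math.sqrt(max(v_int_re, 0.0))},
        "slope": {"variance": v_slope_re, "sd": math.sqrt(max(v_slope_re, 0.0))},
        "residual": {"variance": v_resid, "sd": math.sqrt(v_resid)},
    }

    params = res.params
    conf = res.conf_int()
    sd_y = float(y.std(ddof=1))
    sds = {t: float(df[t].std(ddof=1)) for t in fe_terms}
    fixed = _effects_from_fit(params, res.bse, res.pvalues, conf, fe_terms, sds, sd_y)

    cp = res.cov_params()
    cov_fe = np.array([
        [cp.loc[exposure, exposure], cp.loc[exposure, inter]],
        [cp.loc[inter, exposure], cp.loc[inter, inter]],
    ])
    mu_age, sd_age = scaling.get(age, (0.0, 1.0))
    return TrajectoryFit(
        fixed=fixed, variance_components=vc, converged=bool(res.converged),
        method="REML", exposure=exposure, interaction=inter, moderator=age,
        b_exp=float(params[exposure]), b_int=float(params[inter]), cov_fe=cov_fe,
        age_center=mu_age, age_scale=sd_age,
        observed_moderator=np.unique(df[age].to_numpy()),
        n_persons=int(df[person].nunique()), n_obs=int(len(df)),
    )


# ---------------------------------------------------------------------------
# Johnson-Neyman regions
# ---------------------------------------------------------------------------

def jn_boundaries(b_exp: float, b_int: float, v_exp: float, v_int: float,
                  cov: float, t_crit: float) -> list[float]:
    """Moderator values where the conditional slope is exactly borderline.

    Solves ``(b_exp + a * b_int)^2 = t^2 * (v_exp + a^2 v_int + 2 a cov)``,
    a quadratic in the moderator ``a``; returns its real roots sorted
    ascending (empty when the discriminant is negative or the equation is
    degenerate).
    """
    A = b_int**2 - t_crit**2 * v_int
    B = 2 * (b_exp * b_int - t_crit**2 * cov)
    C = b_exp**2 - t_crit**2 * v_exp
    if abs(A) < 1e-300:
        if abs(B) < 1e-300:
            return []
        return [-C / B]
    disc = B * B - 4 * A * C
    if disc < 0:
        return []
    r = math.sqrt(disc)
    return sorted([(-B - r) / (2 * A), (-B + r) / (2 * A)])


@dataclass
class JNResult:
    """Johnson-Neyman regions of significance for the exposure x age interaction."""

    grid: np.ndarray
    conditional_slope: np.ndarray
    se: np.ndarray
    p: np.ndarray
    alpha: float
    adjusted_alpha: float
    t_crit: float
    fdr: bool
    boundaries: list[float]            # scaled-moderator values inside the observed range
    regions: list[tuple[float, float]]  # significant intervals, scaled moderator
    age_center: float
    age_scale: float

    def boundaries_age(self) -> list[float]:
        """Boundaries on the original age scale (years)."""
        return [b * self.age_scale + self.age_center for b in self.boundaries]

    def regions_age(self) -> list[tuple[float, float]]:
        return [(lo * self.age_scale + self.age_center, hi * self.age_scale + self.age_center)
                for lo, hi in self.regions]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "adjusted_alpha": self.adjusted_alpha,
            "t_crit": self.t_crit, "fdr": self.fdr,
            "boundaries_age": self.boundaries_age(),
            "regions_age": self.regions_age(),
        }


def johnson_neyman(
    fit: TrajectoryFit,
    alpha: float = 0.05,
    fdr: bool = True,
    n_grid: int = 200,
) -> JNResult:
    """Regions of age where the conditional NSD slope is significant.

    The conditional slope at scaled age ``a`` is ``b_exp + a * b_int`` with
    standard error from the fixed-effect covariance.  Without FDR the
    boundaries solve the borderline quadratic at the normal critical value
    for ``alpha``.  With ``fdr=True`` the Benjamini-Hochberg step-up over the
    grid of observed ages (plus ``n_grid`` equal steps across the observed
    range) determines an adjusted critical value — the largest raw p declared
    significant by BH — and the boundaries are re-solved at that stricter
    threshold, so FDR regions are always subsets of unadjusted ones.
    """
    if fit.b_int is None or not np.isfinite(fit.b_int):
        raise ValueError("fit carries no interaction term; Johnson-Neyman undefined")
    obs = np.asarray(fit.observed_moderator, dtype=float)
    lo, hi = float(obs.min()), float(obs.max())
    grid = np.unique(np.concatenate([obs, np.linspace(lo, hi, n_grid)]))

    v_e, v_i = fit.cov_fe[0, 0], fit.cov_fe[1, 1]
    c_ei = fit.cov_fe[0, 1]
    slope = fit.b_exp + grid * fit.b_int
    se = np.sqrt(v_e + grid**2 * v_i + 2 * grid * c_ei)
    z = slope / se
    p = 2 * stats.norm.sf(np.abs(z))

    if fdr:
        reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")[0:4]
        if reject.any():
            adjusted_alpha = float(p[reject].max())
        else:
            adjusted_alpha = 0.0
    else:
        adjusted_alpha = alpha

    if adjusted_alpha <= 0.0:
        t_crit = math.inf
        bounds: list[float] = []
        regions: list[tuple[float, float]] = []
    else:
        t_crit = float(stats.norm.ppf(1 - adjusted_alpha / 2))
        roots = jn_boundaries(fit.b_exp, fit.b_int, v_e, v_i, c_ei, t_crit)
        bounds = [r for r in roots if lo < r < hi]
        # classify sub-intervals of the observed range by their midpoints
        edges = [lo] + bounds + [hi]
        regions = []
        for k in range(len(edges) - 1):
            mid = 0.5 * (edges[k] + edges[k + 1])
            s_mid = fit.b_exp + mid * fit.b_int
            se_mid = math.sqrt(v_e + mid**2 * v_i + 2 * mid * c_ei)
            if abs(s_mid / se_mid) > t_crit:
                regions.append((edges[k], edges[k + 1]))

    return JNResult(
        grid=grid, conditional_slope=slope, se=se, p=p,
        alpha=alpha, adjusted_alpha=adjusted_alpha, t_crit=t_crit, fdr=fdr,
        boundaries=bounds, regions=regions,
        age_center=fit.age_center, age_scale=fit.age_scale,
    )


# ---------------------------------------------------------------------------
# sex interaction & logistic sensitivity variants
# ---------------------------------------------------------------------------

def sex_interaction_test(
    data: pd.DataFrame,
    exposure: str,
    confounders: ConfounderSet,
    sex: str = "sex",
    outcome: str = "fi",
    which: str = "baseline",
    age: str = "age",
    person: str = "person_id",
) -> EffectEstimate:
    """Confirmatory sex x NSD interaction in the total (unstratified) sample.

    ``which="baseline"`` adds sex and sex x exposure to the stage-2 linear
    model and reports the interaction; ``which="trajectory"`` adds the
    sex x exposure x age term to the mixed model and reports the three-way
    interaction (differential progression by sex).
    """
    if data[sex].nunique() < 2:
        raise ValueError("both sexes must be present to test a sex interaction")

    if which == "baseline":
        terms = [exposure] + [c for c in confounders.all_terms] + [sex]
        df, X, y, sds, _ = _prepare(data, terms, outcome)
        inter = f"{sex}:{exposure}"
        X[inter] = X[sex] * X[exposure]
        _check_rank(X)
        res = sm.OLS(y, X).fit()
        conf = res.conf_int()
        return _effects_from_fit(res.params, res.bse, res.pvalues, conf, [inter],
                                 {inter: float(X[inter].std(ddof=1))},
                                 float(y.std(ddof=1)))[0]

    if which != "trajectory":
        raise ValueError("which must be 'baseline' or 'trajectory'")
    cols = list(dict.fromkeys([person, exposure, age, sex, outcome]
                              + list(confounders.all_terms)))
    df = data[cols].dropna().copy()
    for t in [exposure, age] + [c for c in confounders.all_terms if c != age]:
        s = pd.to_numeric(df[t])
        if not _is_binary(s):
            df[t] = (s - s.mean()) / s.std(ddof=1)
        else:
            df[t] = s.astype(float)
    df[sex] = pd.to_numeric(df[sex]).astype(float)
    fe = [exposure, age, sex] + [c for c in confounders.all_terms if c != age]
    df["exp:age"] = df[exposure] * df[age]
    df["sex:exp"] = df[sex] * df[exposure]
    df["sex:age"] = df[sex] * df[age]
    df["sex:exp:age"] = df[sex] * df[exposure] * df[age]
    fe += ["exp:age", "sex:exp", "sex:age", "sex:exp:age"]
    X = sm.add_constant(df[fe], has_constant="add")
    _check_rank(X)
    y = pd.to_numeric(df[outcome]).astype(float)
    model = sm.MixedLM(y, X, groups=df[person],
                       exog_re=sm.add_constant(df[[age]], has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(reml=True, method=["lbfgs", "cg"])
    conf = res.conf_int()
    t = "sex:exp:age"
    return _effects_from_fit(res.params, res.bse, res.pvalues, conf, [t],
                             {t: float(df[t].std(ddof=1))}, float(y.std(ddof=1)))[0]


def fit_binary(
    data: pd.DataFrame,
    exposure: str,
    confounders: ConfounderSet,
    cutpoint: float = 0.2,
    outcome: str = "fi",
    progression: bool = False,
    age: str = "age",
    person: str = "person_id",
) -> list[EffectEstimate]:
    """Logistic sensitivity analysis on the dichotomized Frailty Index.

    The outcome is 1 ("frail") when FI >= ``cutpoint``.  Baseline uses plain
    logistic regression; ``progression=True`` uses a variational mixed
    logistic model with random intercepts and age slopes and an exposure x
    age term.  Estimates are odds ratios with exponentiated Wald 95% CIs
    (``b`` holds the OR; ``beta`` is left None on the odds scale).  Requires
    at least 10 events and 10 non-events; perfect separation raises
    :class:`SeparationError` suggesting a penalized fit.
    """
    d = data.copy()
    d["_frail"] = (pd.to_numeric(d[outcome]) >= cutpoint).astype(float)
    d.loc[d[outcome].isna(), "_frail"] = np.nan
    events = d["_frail"].sum()
    nonevents = (d["_frail"] == 0).sum()
    if events < 10 or nonevents < 10:
        raise ValueError(f"too few events for logistic fit ({int(events)} frail, "
                         f"{int(nonevents)} robust)")

    if not progression:
        terms = [exposure] + confounders.all_terms
        df, X, y, sds, _ = _prepare(d, terms, "_frail")
        _check_rank(X)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = sm.Logit(y, X).fit(disp=0)
        except (PerfectSeparationError, RuntimeWarning) as exc:
            raise SeparationError(
                "perfect separation in logistic fit; consider a penalized fallback"
            ) from exc
        conf = res.conf_int()
        out = []
        for t in terms:
            out.append(EffectEstimate(
                term=t, b=float(np.exp(res.params[t])),
                ci_low=float(np.exp(conf.loc[t, 0])), ci_high=float(np.exp(conf.loc[t, 1])),
                p_value=float(res.pvalues[t]), beta=None))
        return out

    # progression: variational Bayes mixed logistic with intercept+slope effects
    terms = [exposure, age] + [c for c in confounders.all_terms if c != age]
    cols = list(dict.fromkeys([person] + terms + ["_frail"]))
    df = d[cols].dropna().copy()
    for t in terms:
        s = pd.to_numeric(df[t])
        if not _is_binary(s):
            df[t] = (s - s.mean()) / s.std(ddof=1)
        else:
            df[t] = s.astype(float)
    inter = f"{exposure}:{age}"
    df[inter] = df[exposure] * df[age]
    fe = terms + [inter]
    X = sm.add_constant(df[fe], has_constant="add")
    _check_rank(X)
    groups = df[person].astype(str)
    codes, _ = pd.factorize(groups)
    n_g = codes.max() + 1
    import scipy.sparse as sp
    Zi = sp.csr_matrix((np.ones(len(df)), (np.arange(len(df)), codes)), shape=(len(df), n_g))
    Zs = sp.csr_matrix((df[age].to_numpy(), (np.arange(len(df)), codes)), shape=(len(df), n_g))
    exog_vc = sp.hstack([Zi, Zs]).tocsr()
    ident = np.concatenate([np.zeros(n_g, dtype=int), np.ones(n_g, dtype=int)])
    model = sm.BinomialBayesMixedGLM(df["_frail"].to_numpy(), X.to_numpy(), exog_vc, ident,
                                     vcp_p=2.0, fe_p=2.0)
    res = model.fit_vb()
    out = []
    z = stats.norm.ppf(0.975)
    for i, t in enumerate(["const"] + fe):
        if t == "const":
            continue
        b, se = float(res.fe_mean[i]), float(res.fe_sd[i])
        out.append(EffectEstimate(
            term=t, b=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)), ci_high=float(np.exp(b + z * se)),
            p_value=float(2 * stats.norm.sf(abs(b / se))), beta=None))
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
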