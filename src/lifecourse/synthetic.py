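"""Synthetic life-course cohorts with a known true generating model.

The generator emulates the structure of a birth cohort followed from age 70
over five triennial waves, with retrospectively recalled residential
histories linked to decade-level neighborhood social deprivation (NSD):

* per-person decade NSD series are Gaussian with AR(1) dependence across
  decades, with declining population means across life (childhood mean
  +0.41, young adulthood -0.64, mid-to-late adulthood -1.95 on the ward
  z-score scale, sds about 3.3 / 2.6 / 2.8);
* frailty rises across waves (baseline mean 0.14) under a linear
  random-intercept/random-slope model in scaled age, with one configurable
  *true* life-course variable driving baseline frailty and/or its slope;
* deficits are conditionally independent Bernoulli draws given the latent
  frailty level, so the Frailty Index (sum over items / items) recovers the
  latent value in expectation;
* monotone wave-on-wave attrition thins later waves (default retention
  ladder 1.00, 1.00, 0.97, 0.84, 0.66 relative to wave 1).

The emitted ward table is an encoding device, not a geography: every person-
decade receives its own ward whose raw index equals the person's drawn NSD
value, plus unlisted padding wards that pin the decade's ward-level mean to 0
and sample sd to 1, so that the pipeline's within-decade z-scoring is the
identity and recovers the generated exposures exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frailty as frailty_mod

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_true_params",
    "effect_for_standardized_beta",
    "recovery_experiment",
]

DECADES = (1941, 1951, 1961, 1971, 1981, 1991, 2001, 2011)

_LIFE_COURSE_MODELS = (
    "sp_child", "sp_young", "sp_midlate", "accumulation", "em_early", "em_late", "null",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults mirror the study conditions."""

    n_persons: int = 323
    sex_ratio: float = 0.5              # probability of male (sex=1)
    decade_nsd_means: tuple = (0.41, 0.41, -0.64, -0.64, -1.95, -1.95, -1.95, -1.95)
    decade_nsd_sds: tuple = (3.29, 3.29, 2.61, 2.61, 2.78, 2.78, 2.78, 2.78)
    within_person_decade_correlation: float = 0.6
    history_missing_rate: float = 0.1   # person-decade addresses lost / outside area
    true_model: str = "null"
    true_effect_baseline: float = 0.0   # FI units per 1 sd of the true variable
    true_effect_slope: float = 0.0      # FI units per sd exposure per sd age
    confounder_effects: dict = field(default_factory=lambda: {
        "iq_age11": -0.010, "education_years": -0.010, "childhood_smoking": 0.010,
        "parental_osc": 0.010, "adult_osc": 0.005, "current_smoking": 0.010, "sex": 0.0,
    })
    population_slope: float = 0.028     # FI change per 1 sd of age
    random_intercept_sd: float = 0.06
    random_slope_sd: float = 0.022
    residual_sd: float = 0.037
    wave_ages: tuple = (70, 73, 76, 79, 82)
    age_jitter_sd: float = 0.75
    attrition: tuple = (1.0, 1.0, 313 / 323, 270 / 323, 212 / 323)
    frailty_baseline_mean: float = 0.14
    n_deficits: int = 30
    cognitive_impairment_rate: float = 10 / 323
    seed: int = 0

    def __post_init__(self):
        if self.true_model not in _LIFE_COURSE_MODELS:
            raise ValueError(f"true_model must be one of {_LIFE_COURSE_MODELS}")
        if not (0 <= self.within_person_decade_correlation < 1):
            raise ValueError("within_person_decade_correlation must be in [0, 1)")
        if any(not (0 <= r <= 1) for r in self.attrition):
            raise ValueError("attrition retention probabilities must be in [0, 1]")
        if min(self.random_intercept_sd, self.random_slope_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if list(self.wave_ages) != sorted(set(self.wave_ages)):
            raise ValueError("wave_ages must be strictly increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("decade_nsd_means", "decade_nsd_sds", "wave_ages", "attrition"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in ("decade_nsd_means", "decade_nsd_sds", "wave_ages", "attrition"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Cohort:
    """In-memory synthetic cohort: the four pipeline input tables plus truth."""

    assessments: pd.DataFrame
    history: pd.DataFrame
    wards: pd.DataFrame
    covariates: pd.DataFrame
    true_params: dict


def effect_for_standardized_beta(cfg: GeneratorConfig, beta: float) -> float:
    """Baseline effect (FI units per sd exposure) giving standardized beta.

    Uses the generator's noise budget: random intercept, residual, item-level
    binomial noise at the baseline mean, and the confounder contributions
    (each effect is per sd of a centred confounder, so contributes its
    square).  Solves ``b = beta * sd_y`` with ``sd_y^2 = b^2 + noise^2``.
    """
    p = cfg.frailty_baseline_mean
    noise2 = (cfg.random_intercept_sd**2 + cfg.residual_sd**2
              + p * (1 - p) / cfg.n_deficits
              + sum(v**2 for v in cfg.confounder_effects.values()))
    if not (0 <= beta < 1):
        raise ValueError("standardized beta must be in [0, 1)")
    return beta * np.sqrt(noise2 / (1 - beta**2))


def _standardized(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _padding_wards(values: np.ndarray) -> np.ndarray:
    """Padding ward values making [values, padding] have mean 0, sample sd 1.

    With these wards appended, within-decade z-scoring (sample sd) is the
    identity on ``values``.
    """
    n = values.size
    S = float(values.sum())
    Q = float((values**2).sum())
    K = max(2, int(np.ceil(Q - n + 2)))
    while n + K - 1 - Q - S * S / K < 0:   # ensure non-negative excess variance
        K *= 2
    m = -S / K
    excess = n + K - 1 - Q - S * S / K
    t = np.sqrt(excess / 2.0)
    pads = np.full(K, m)
    pads[0] += t
    pads[1] -= t
    return pads


def generate_cohort(cfg: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Draw one synthetic cohort under ``cfg``.

    Returns the four tables the pipeline consumes (assessments with raw
    deficit measures and age, residential history, ward index table,
    covariates) and a ``true_params`` dict that reproduces the draw
    bit-identically via :class:`GeneratorConfig` round-trip.
    """
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    n_dec = len(DECADES)
    persons = np.array([f"p{i:05d}" for i in range(1, n + 1)])

    # --- decade NSD series: Gaussian AR(1) around decade means ---------------
    rho = cfg.within_person_decade_correlation
    lag = np.abs(np.subtract.outer(np.arange(n_dec), np.arange(n_dec)))
    L = np.linalg.cholesky(rho**lag)
    Z = rng.standard_normal((n, n_dec)) @ L.T
    nsd = np.asarray(cfg.decade_nsd_means) + Z * np.asarray(cfg.decade_nsd_sds)

    # --- true life-course variable (from the full lived series) --------------
    child = nsd[:, 0:2].mean(axis=1)
    young = nsd[:, 2:4].mean(axis=1)
    midlate = nsd[:, 4:8].mean(axis=1)
    encoded = {
        "sp_child": child, "sp_young": young, "sp_midlate": midlate,
        "accumulation": (child + young + midlate) / 3.0,
        "em_early": (child + 10.0) * (young + 10.0),
        "em_late": (young + 10.0) * (midlate + 10.0),
    }
    if cfg.true_model == "null":
        x_std = np.zeros(n)
    else:
        x_std = _standardized(encoded[cfg.true_model])

    # --- covariates -----------------------------------------------------------
    cov = pd.DataFrame({
        "person_id": persons,
        "sex": (rng.random(n) < cfg.sex_ratio).astype(int),          # 1 = male
        "parental_osc": (rng.random(n) < 0.73).astype(int),          # 1 = class III-V
        "iq_age11": rng.normal(100.0, 15.0, n),
        "education_years": rng.normal(10.64, 1.06, n),
        "childhood_smoking": (rng.random(n) < 0.19).astype(int),
        "adult_osc": (rng.random(n) < 0.45).astype(int),
        "current_smoking": (rng.random(n) < 0.07).astype(int),
        "cognitive_impairment": (rng.random(n) < cfg.cognitive_impairment_rate).astype(int),
    })
    conf_term = np.zeros(n)
    for name, eff in cfg.confounder_effects.items():
        if eff == 0.0 or name not in cov.columns:
            continue
        v = cov[name].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        conf_term += eff * ((v - v.mean()) / sd if sd > 0 else 0.0)

    # --- frailty trajectories -------------------------------------------------
    wave_ages = np.asarray(cfg.wave_ages, dtype=float)
    age_center = wave_ages.mean()
    age_scale = wave_ages.std(ddof=1)
    s_w1 = (wave_ages[0] - age_center) / age_scale
    intercept0 = cfg.frailty_baseline_mean - cfg.population_slope * s_w1

    u0 = rng.normal(0.0, cfg.random_intercept_sd, n)
    u1 = rng.normal(0.0, cfg.random_slope_sd, n)
    jitter = rng.normal(0.0, cfg.age_jitter_sd, n)

    base = intercept0 + cfg.true_effect_baseline * x_std + conf_term + u0
    slope = cfg.population_slope + cfg.true_effect_slope * x_std + u1

    n_waves = len(cfg.wave_ages)
    ages = wave_ages[None, :] + jitter[:, None]
    s_age = (ages - age_center) / age_scale
    eps = rng.normal(0.0, cfg.residual_sd, (n, n_waves))
    latent = base[:, None] + slope[:, None] * s_age + eps
    clipped_frac = float(np.mean((latent < 0) | (latent > 1)))
    if clipped_frac > 0.05:
        warnings.warn(f"latent frailty clipped in {clipped_frac:.1%} of person-waves; "
                      "check effect sizes and variance components", stacklevel=2)
    latent = np.clip(latent, 0.0, 1.0)

    # --- monotone attrition ---------------------------------------------------
    retention = np.asarray(cfg.attrition, dtype=float)
    present = np.ones((n, n_waves), dtype=bool)
    for w in range(n_waves):
        r_prev = retention[w - 1] if w > 0 else 1.0
        p_cont = retention[w] / r_prev if r_prev > 0 else 0.0
        stay = rng.random(n) < p_cont
        present[:, w] = present[:, w - 1] & stay if w > 0 else stay

    # --- deficits: independent Bernoulli given latent frailty ----------------
    deficits = rng.random((n, n_waves, cfg.n_deficits)) < latent[:, :, None]

    rows = []
    for w in range(n_waves):
        idx = np.flatnonzero(present[:, w])
        block = pd.DataFrame({
            "person_id": persons[idx],
            "wave": w + 1,
            "age": ages[idx, w],
        })
        for j in range(cfg.n_deficits):
            block[f"d{j + 1:02d}"] = deficits[idx, w, j].astype(int)
        rows.append(block)
    assessments = pd.concat(rows, ignore_index=True)

    # --- residential history & ward table (z-scoring-identity encoding) -----
    has_decade = rng.random((n, n_dec)) >= cfg.history_missing_rate
    hist_rows, ward_rows = [], []
    for d_idx, decade in enumerate(DECADES):
        idx = np.flatnonzero(has_decade[:, d_idx])
        if idx.size == 0:
            continue
        vals = nsd[idx, d_idx]
        wids = np.array([f"w{decade}_{persons[i]}" for i in idx])
        hist_rows.append(pd.DataFrame({
            "person_id": persons[idx], "decade_year": decade, "ward_id": wids,
        }))
        pads = _padding_wards(vals)
        ward_rows.append(pd.DataFrame({
            "ward_id": np.concatenate([wids, [f"pad{decade}_{k}" for k in range(pads.size)]]),
            "decade_year": decade,
            "raw_index": np.concatenate([vals, pads]),
        }))
    history = pd.concat(hist_rows, ignore_index=True)
    wards = pd.concat(ward_rows, ignore_index=True)

    true_params = {
        "config": cfg.to_dict(),
        "decades": list(DECADES),
        "clipped_fraction": clipped_frac,
    }
    return Cohort(assessments=assessments, history=history, wards=wards,
                  covariates=cov, true_params=true_params)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write the four CSVs plus ``true_params.json``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("assessments", "history", "wards", "covariates"):
        p = out / f"{name}.csv"
        getattr(cohort, name).to_csv(p, index=False)
        paths[name] = p
    p = out / "true_params.json"
    with open(p, "w") as fh:
        json.dump(cohort.true_params, fh, indent=1, sort_keys=True)
    paths["true_params"] = p
    return paths


def read_true_params(path) -> GeneratorConfig:
    """Reload a generator config from a ``true_params.json`` file."""
    with open(path) as fh:
        d = json.load(fh)
    return GeneratorConfig.from_dict(d["config"])


def recovery_experiment(
    cfg_grid,
    n_replicates: int,
    seed: int = 0,
    alpha: float = 0.05,
    collinearity_threshold: float = 0.9,
    stage2: bool = False,
) -> pd.DataFrame:
    """Selection-recovery (and optionally estimation-recovery) simulation.

    For each config in ``cfg_grid``, generates ``n_replicates`` cohorts, runs
    the full stage-1 pipeline (frailty scoring, exposure encoding,
    residualization on the common confounders, collinearity screen,
    LARS/lasso path, covariance test) and tabulates how often each candidate
    is first-selected and how often the first step is supported at
    ``alpha``.  With ``stage2=True`` the trajectory mixed model is also fitted
    for the true exposure and interaction bias / CI coverage recorded.
    Replicates whose pipeline fails are logged and excluded (``n_failed``).
    """
    from .pipeline import run_stage1  # deferred: pipeline imports are heavier

    ss = np.random.SeedSequence(seed)
    records = []
    for cfg in cfg_grid:
        child_seeds = ss.spawn(1)[0].generate_state(n_replicates)
        first = {}
        supported = 0
        n_ok = 0
        n_failed = 0
        biases, covered = [], 0
        for r in range(n_replicates):
            rep_seed = int(child_seeds[r] % (2**31 - 1))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    cohort = generate_cohort(cfg, seed=rep_seed)
                    sel, tables = run_stage1(
                        cohort.assessments, cohort.history, cohort.wards,
                        cohort.covariates, alpha=alpha,
                        collinearity_threshold=collinearity_threshold,
                    )
                    if stage2 and cfg.true_model != "null":
                        from .estimation import confounder_set_for, fit_trajectory
                        cs = confounder_set_for(cfg.true_model)
                        fit = fit_trajectory(tables["long"], cfg.true_model, cs)
                        est = next(e for e in fit.fixed if e.term == fit.interaction)
                        # convert to generator age units: the fit scales age by
                        # the attrition-weighted sample sd, the generator by the
                        # wave-age sd; the conversion is an exact linear rescale
                        k = float(np.std(cfg.wave_ages, ddof=1)) / fit.age_scale
                        biases.append(est.b * k - cfg.true_effect_slope)
                        covered += int(est.ci_low * k <= cfg.true_effect_slope
                                       <= est.ci_high * k)
                first[sel.first_selected] = first.get(sel.first_selected, 0) + 1
                supported += int(sel.supported)
                n_ok += 1
            except Exception as exc:     # noqa: BLE001 - replicate-level robustness
                n_failed += 1
                warnings.warn(f"replicate {r} failed: {exc}", stacklevel=2)
        rec = {
            "true_model": cfg.true_model,
            "true_effect_baseline": cfg.true_effect_baseline,
            "true_effect_slope": cfg.true_effect_slope,
            "n_persons": cfg.n_persons,
            "n_replicates": n_ok,
            "n_failed": n_failed,
            "support_rate": supported / n_ok if n_ok else np.nan,
        }
        for name in ("sp_child", "sp_young", "sp_midlate", "accumulation",
                     "em_early", "em_late"):
            rec[f"first_{name}"] = first.get(name, 0) / n_ok if n_ok else np.nan
        if stage2 and biases:
            rec["interaction_bias"] = float(np.mean(biases))
            rec["interaction_coverage"] = covered / len(biases)
        records.append(rec)
    return pd.DataFrame(records)
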