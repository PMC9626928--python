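"""End-to-end orchestration: frailty -> exposure -> selection -> estimation.

Mirrors the analysis design of a sex-stratified structured life-course study:
stage 1 selects the best-fitting life-course model per stratum from the
LARS/lasso path with the covariance test, stage 2 estimates baseline and
trajectory associations for the selected exposure under the DAG-appropriate
confounder set, with Johnson-Neyman age regions and a confirmatory sex x
exposure interaction in the total sample.  Sensitivity toggles cover
life-course-specific residualization, sample restriction, exposure
truncation, tertile exposures, the dichotomized frailty outcome, and
exclusion flags.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import EmptyStratumError
from .exposure import (DEFAULT_PERIODS, PeriodDefinitions, encode_life_course,
                       link_decades, period_means, tertile_encode, zscore_by_decade)
from .frailty import DeficitSchema, default_schema, frailty_table
from .selection import (covariance_test, drop_collinear, lars_path, residualize,
                        select_model)
from .estimation import (confounder_set_for, standard_confounder_sets,
                         fit_baseline, fit_binary, fit_trajectory,
                         johnson_neyman, sex_interaction_test)

__all__ = [
    "CANDIDATES",
    "AnalysisConfig",
    "run_stage1",
    "run_analysis",
    "analyze_tables",
    "sample_flow",
    "count_percent",
]

logger = logging.getLogger(__name__)

CANDIDATES = ("sp_child", "sp_young", "sp_midlate", "accumulation", "em_early", "em_late")


def count_percent(counts: dict[str, int], decimals: int = 2) -> dict[str, dict]:
    """Category counts -> percentages of the column total (printed precision)."""
    total = sum(counts.values())
    return {k: {"n": int(v), "pct": round(100.0 * v / total, decimals)}
            for k, v in counts.items()}


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    assessments: str | None = None
    history: str | None = None
    wards: str | None = None
    covariates: str | None = None
    schema: str | None = None                     # YAML deficit schema (None -> default)
    out_dir: str | None = None
    periods: PeriodDefinitions = field(default_factory=PeriodDefinitions)
    candidates: tuple = CANDIDATES
    stage1_confounders: tuple = ("age", "parental_osc")
    alpha: float = 0.05
    fdr: bool = True
    collinearity_threshold: float = 0.9
    min_observed_fraction: float = 0.8
    stratify_by_sex: bool = True
    seed: int = 0
    # sensitivity toggles
    residualize_specific: bool = False
    restrict_full_history: bool = False
    truncation_year: int | None = None
    tertiles: bool = False
    binary_outcome: bool = False
    binary_cutpoint: float = 0.2
    exclude_flag: str | None = None               # covariate column; 1 -> excluded

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "periods" in raw and isinstance(raw["periods"], dict):
            raw["periods"] = PeriodDefinitions(**{k: tuple(v) for k, v in raw["periods"].items()})
        for k in ("candidates", "stage1_confounders"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def sample_flow(persons: pd.DataFrame, rules: list[tuple[str, object]]) -> list[dict]:
    """Apply ordered eligibility rules, counting survivors after each.

    ``rules`` are ``(name, predicate)`` pairs where the predicate maps the
    current frame to a boolean keep-mask.  Exclusion reasons are logged per
    rule; counts are non-increasing along the flow.
    """
    flow = [{"rule": "input", "n": int(len(persons))}]
    cur = persons
    for name, pred in rules:
        mask = np.asarray(pred(cur), dtype=bool)
        n_drop = int((~mask).sum())
        if n_drop:
            logger.info("rule %r excluded %d persons", name, n_drop)
        cur = cur.loc[mask]
        flow.append({"rule": name, "n": int(len(cur))})
    return flow


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def run_stage1(
    assessments: pd.DataFrame,
    history: pd.DataFrame,
    wards: pd.DataFrame,
    covariates: pd.DataFrame,
    schema: DeficitSchema | None = None,
    periods: PeriodDefinitions = DEFAULT_PERIODS,
    candidates=CANDIDATES,
    confounders=("age", "parental_osc"),
    alpha: float = 0.05,
    collinearity_threshold: float = 0.9,
    min_observed_fraction: float = 0.8,
    residualize_specific: bool = False,
):
    """Frailty scoring, exposure encoding and LARS/lasso selection for one sample.

    Returns ``(SelectionResult, tables)`` where ``tables`` carries the
    intermediate frames: per-wave frailty, encoded life-course variables, the
    merged wave-1 analysis frame, the person-wave long frame for stage 2, and
    the collinearity drop log.
    """
    schema = schema or default_schema()
    fi = frailty_table(assessments, schema, min_observed_fraction)
    z = zscore_by_decade(wards)
    decade_exposure = link_decades(history, z)
    pm = period_means(decade_exposure, periods)
    lc = encode_life_course(pm)

    w1 = fi[(fi["wave"] == 1) & fi["valid"]][["person_id", "age", "fi"]]
    merged = lc.merge(w1, on="person_id", how="inner").merge(
        covariates, on="person_id", how="left")
    need = list(candidates) + ["fi"] + [c for c in confounders if c in merged.columns]
    merged = merged.dropna(subset=need).reset_index(drop=True)
    if merged.empty:
        raise EmptyStratumError("no complete-case rows for stage 1")

    X = merged[list(candidates)]
    if residualize_specific:
        parts = {}
        for cand in candidates:
            cs = confounder_set_for(cand)
            cvars = [v for v in cs.all_terms if v in merged.columns and v not in candidates]
            parts[cand] = residualize(merged[[cand]], merged[cvars])[cand]
        Xr = pd.DataFrame(parts)
    else:
        C = merged[[c for c in confounders if c in merged.columns]]
        Xr = residualize(X, C)
    Xk, drop_log = drop_collinear(Xr, threshold=collinearity_threshold)
    path = lars_path(Xk, merged["fi"])
    cov = covariance_test(path, Xk, merged["fi"])
    sel = select_model(path, cov, alpha=alpha)

    long = (fi[fi["valid"]]
            .merge(lc, on="person_id", how="inner")
            .merge(covariates, on="person_id", how="left"))
    tables = {"fi": fi, "life_course": lc, "decade_exposure": decade_exposure,
              "merged": merged, "long": long, "drop_log": drop_log}
    return sel, tables


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _stage2_for_stratum(sel, tables, cfg: AnalysisConfig) -> dict:
    exposure = sel.first_selected
    cs = confounder_set_for(exposure)
    # the prior-period variable must exist in the data to be used
    if cs.prior_period_nsd and cs.prior_period_nsd not in tables["merged"].columns:
        cs = cs.with_prior(None)
    merged, long = tables["merged"], tables["long"]
    # a confounder without variation in this stratum cannot adjust anything
    # and would make the design rank deficient; drop it with a log line
    constant = tuple(v for v in cs.variables
                     if v in merged.columns and merged[v].dropna().nunique() < 2)
    if constant:
        logger.warning("dropping constant confounders in stratum: %s", list(constant))
        cs = dataclasses.replace(cs, variables=tuple(v for v in cs.variables
                                                     if v not in constant))
    out: dict = {"exposure": exposure, "confounder_set": cs.label,
                 "prior_period_adjustment": cs.prior_period_nsd,
                 "dropped_constant_confounders": list(constant)}
    baseline = fit_baseline(merged, exposure, cs)
    out["baseline"] = [e.to_dict() for e in baseline]

    traj = fit_trajectory(long, exposure, cs)
    out["trajectory"] = traj.to_dict()
    jn = johnson_neyman(traj, alpha=cfg.alpha, fdr=cfg.fdr)
    out["johnson_neyman"] = jn.to_dict()

    if cfg.tertiles:
        m = merged.copy()
        cats = tertile_encode(m[exposure])
        m["tert_moderate"] = (np.asarray(cats) == "moderate").astype(float)
        m["tert_high"] = (np.asarray(cats) == "high").astype(float)
        tert_effects = []
        for dummy in ("tert_moderate", "tert_high"):
            eff = fit_baseline(m, dummy, cs)
            tert_effects.append(eff[0].to_dict())
        out["tertile_baseline"] = tert_effects

    if cfg.binary_outcome:
        try:
            out["binary_baseline"] = [e.to_dict() for e in
                                      fit_binary(merged, exposure, cs,
                                                 cutpoint=cfg.binary_cutpoint)]
            out["binary_progression"] = [e.to_dict() for e in
                                         fit_binary(long, exposure, cs,
                                                    cutpoint=cfg.binary_cutpoint,
                                                    progression=True)]
        except ValueError as exc:
            out["binary_error"] = str(exc)
    return out


def analyze_tables(
    assessments: pd.DataFrame,
    history: pd.DataFrame,
    wards: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: AnalysisConfig,
    schema: DeficitSchema | None = None,
) -> dict:
    """Run the full analysis on in-memory tables; returns the report dict."""
    periods = cfg.periods
    if cfg.truncation_year is not None:
        periods = periods.truncated(cfg.truncation_year)

    cov = covariates.copy()
    rules: list[tuple[str, object]] = []
    if cfg.exclude_flag:
        rules.append((f"no_{cfg.exclude_flag}",
                      lambda df, f=cfg.exclude_flag: df[f].fillna(0) == 0))
    if cfg.restrict_full_history:
        full = history.groupby("person_id")["decade_year"].nunique()
        complete = set(full[full == full.max()].index)
        rules.append(("full_residential_history",
                      lambda df: df["person_id"].isin(complete)))
    flow = sample_flow(cov, rules)
    for name, pred in rules:
        cov = cov.loc[np.asarray(pred(cov), dtype=bool)]

    strata: dict[str, pd.DataFrame] = {}
    if cfg.stratify_by_sex and "sex" in cov.columns:
        strata["male"] = cov[cov["sex"] == 1]
        strata["female"] = cov[cov["sex"] == 0]
    else:
        strata["all"] = cov

    report: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "sample_flow": flow,
        "strata": {},
    }

    stage1_kw = dict(schema=schema, periods=periods, candidates=cfg.candidates,
                     confounders=cfg.stage1_confounders, alpha=cfg.alpha,
                     collinearity_threshold=cfg.collinearity_threshold,
                     min_observed_fraction=cfg.min_observed_fraction,
                     residualize_specific=cfg.residualize_specific)
    first_by_stratum = {}
    for name, cov_s in strata.items():
        if cov_s.empty:
            raise EmptyStratumError(f"stratum {name!r} contains no persons")
        ids = set(cov_s["person_id"])
        sel, tables = run_stage1(
            assessments[assessments["person_id"].isin(ids)],
            history[history["person_id"].isin(ids)],
            wards, cov_s, **stage1_kw)
        entry = {"n_persons": int(len(tables["merged"])),
                 "selection": sel.to_dict(),
                 "collinearity_drops": tables["drop_log"],
                 "stage2": _stage2_for_stratum(sel, tables, cfg)}
        report["strata"][name] = entry
        first_by_stratum[name] = sel.first_selected

    # confirmatory sex x exposure interaction in the total sample
    if cfg.stratify_by_sex and len(strata) == 2:
        _, tables_all = run_stage1(assessments, history, wards, cov, **stage1_kw)
        report["sex_interaction"] = {}
        for name, expo in first_by_stratum.items():
            cs = confounder_set_for(expo)
            if cs.prior_period_nsd and cs.prior_period_nsd not in tables_all["merged"].columns:
                cs = cs.with_prior(None)
            eff = sex_interaction_test(tables_all["merged"], expo, cs)
            report["sex_interaction"][expo] = eff.to_dict()
    return report


def _config_dict(cfg: AnalysisConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["periods"] = {k: list(v) for k, v in cfg.periods.as_dict().items()}
    d["candidates"] = list(cfg.candidates)
    d["stage1_confounders"] = list(cfg.stage1_confounders)
    return d


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Load the input CSVs named in ``cfg``, run the analysis, write reports.

    Writes ``report.json`` (machine, full precision) and ``report.md``
    (human, rounded) under ``cfg.out_dir`` when set.  Re-running with the
    same config and seed reproduces the JSON byte-identically.
    """
    assessments = pd.read_csv(cfg.assessments)
    history = pd.read_csv(cfg.history)
    wards = pd.read_csv(cfg.wards)
    covariates = pd.read_csv(cfg.covariates)
    schema = DeficitSchema.from_yaml(cfg.schema) if cfg.schema else None
    report = analyze_tables(assessments, history, wards, covariates, cfg, schema=schema)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(out / "report.md", "w") as fh:
            fh.write(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    """Short human-readable summary of a run report (display rounding only)."""
    lines = ["# Life-course NSD and frailty: run report", ""]
    lines.append(f"Package version {report['package_version']}, seed {report['seed']}.")
    lines.append("")
    lines.append("## Sample flow")
    for step in report["sample_flow"]:
        lines.append(f"- {step['rule']}: n = {step['n']}")
    for name, stratum in report["strata"].items():
        sel = stratum["selection"]
        lines.append("")
        lines.append(f"## Stratum: {name} (n = {stratum['n_persons']})")
        lines.append(f"First selected: **{sel['first_selected']}** "
                     f"(supported: {sel['supported']}, "
                     f"R2 first step = {sel['r2_per_step'][0]:.3f})")
        steps = ", ".join(f"{s['variable']} (p={s['p']:.3f})"
                          for s in sel["covariance_test"])
        lines.append(f"Covariance test: {steps}")
        st2 = stratum["stage2"]
        lines.append(f"Stage 2 exposure {st2['exposure']}, "
                     f"confounder set {st2['confounder_set']}.")
        for eff in st2["baseline"][:1]:
            lines.append(f"Baseline b = {eff['b']:.4f} "
                         f"(95% CI {eff['ci_low']:.4f}, {eff['ci_high']:.4f}), "
                         f"beta = {eff['beta']:.3f}")
        for eff in st2["trajectory"]["fixed"]:
            if eff["term"].endswith(":age"):
                lines.append(f"Progression interaction b = {eff['b']:.4f} "
                             f"(95% CI {eff['ci_low']:.4f}, {eff['ci_high']:.4f})")
    if "sex_interaction" in report:
        lines.append("")
        lines.append("## Sex x NSD interaction (total sample)")
        for expo, eff in report["sex_interaction"].items():
            lines.append(f"- {expo}: b = {eff['b']:.4f}, p = {eff['p_value']:.3f}")
    lines.append("")
    return "\n".join(lines)
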