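"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from lifecourse import AnalysisConfig, GeneratorConfig, analyze_tables, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort for structural/contract tests."""
    return generate_cohort(GeneratorConfig(n_persons=120), seed=7)


@pytest.fixture(scope="session")
def effect_cohort():
    """A cohort with a known non-null generating model."""
    cfg = GeneratorConfig(
        n_persons=200,
        true_model="accumulation",
        true_effect_baseline=0.03,
        true_effect_slope=0.005,
    )
    return generate_cohort(cfg, seed=21)


@pytest.fixture(scope="session")
def full_report(effect_cohort):
    """One full sex-stratified analysis report on in-memory tables."""
    cfg = AnalysisConfig(seed=21)
    return analyze_tables(
        effect_cohort.assessments,
        effect_cohort.history,
        effect_cohort.wards,
        effect_cohort.covariates,
        cfg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regression_frame(n=500, b=0.02, noise=0.05, seed=0):
    """Simple linear outcome frame with age + a binary confounder."""
    r = np.random.default_rng(seed)
    x = r.normal(0.0, 2.0, n)
    age = r.normal(70.0, 0.8, n)
    parental = (r.random(n) < 0.7).astype(int)
    y = 0.14 + b * x + 0.01 * parental + r.normal(0.0, noise, n)
    return pd.DataFrame(
        {"person_id": [f"p{i}" for i in range(n)], "fi": y, "expo": x,
         "age": age, "parental_osc": parental}
    )
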