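"""Shared fixtures: synthetic cohorts and fitted multistate models.

The expensive fitted objects are session-scoped so the oracle, effect-
direction, and standardization tests share one MCMC run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from cvdtraj.cohort import GeneratorConfig, generate_cohort
from cvdtraj.multistate import (
    ILLNESS_DEATH,
    baseline_table,
    expand_person_period,
    fit_transitions,
)


def raise_null_bases(cfg: GeneratorConfig) -> GeneratorConfig:
    """Raise the per-wave hazards of a null config so a moderate cohort
    accumulates enough events for meaningful curve comparisons."""
    for name, b in (
        ("healthy->AD", 0.02),
        ("healthy->VaD", 0.01),
        ("healthy->death", 0.03),
        ("dementia->death", 0.2),
    ):
        cfg.hazard_params[name]["base"] = b
    return cfg


@pytest.fixture(scope="session")
def null_fit():
    """Covariate-free cohort (n=2000) with fitted transition models.

    All hazard multipliers are 1, slopes equal across classes, and no
    dementia age floor, so events are independent of every covariate;
    the nonparametric and model-based curves must then agree.
    """
    cfg = raise_null_bases(GeneratorConfig.null(n_subjects=2000, seed=42))
    cohort, truth = generate_cohort(cfg)
    groups = truth.set_index("subject_id")["true_class"]
    tables = expand_person_period(cohort, ILLNESS_DEATH, groups=groups)
    posteriors = fit_transitions(
        tables, n_trees=20, n_burn=100, n_draws=200, random_state=5
    )
    return {
        "cohort": cohort,
        "truth": truth,
        "tables": tables,
        "posteriors": posteriors,
        "baseline": baseline_table(cohort).drop(columns="subject_id"),
    }


@pytest.fixture(scope="session")
def effect_fit():
    """Cohort (n=2000) with a 3x accelerated-class hazard on the dementia
    transitions and fitted models with 500 retained draws."""
    cfg = GeneratorConfig(n_subjects=2000, seed=7)
    for tr in ("healthy->AD", "healthy->VaD"):
        cfg.hazard_params[tr]["class"] = {
            "accelerated": 3.0, "average": 1.7, "stable": 1.0
        }
    cohort, truth = generate_cohort(cfg)
    groups = truth.set_index("subject_id")["true_class"]
    tables = expand_person_period(cohort, ILLNESS_DEATH, groups=groups)
    posteriors = fit_transitions(
        tables, n_trees=20, n_burn=150, n_draws=500, random_state=5
    )
    return {
        "cohort": cohort,
        "truth": truth,
        "tables": tables,
        "posteriors": posteriors,
        "baseline": baseline_table(cohort).drop(columns="subject_id"),
    }


def low_noise_config(n_subjects=800, seed=31) -> GeneratorConfig:
    """Constructed trajectory-recovery scenario: midlife entry ages (risk
    far from saturation), cleanly separated per-class slopes, no
    measurement noise, and no binary risk-factor churn."""
    cfg = GeneratorConfig(
        n_subjects=n_subjects, seed=seed, entry_age_range=(40, 60)
    )
    cfg.measurement_noise_sd = {"sbp_mmHg": 0.0, "bmi_kg_m2": 0.0}
    for cls, (sbp, bmi) in {
        "accelerated": (3.0, 0.20),
        "average": (0.8, 0.05),
        "stable": (-1.5, -0.08),
    }.items():
        sp = cfg.slope_params[cls]
        sp["sbp_mmHg_per_year"] = [sbp, 0.05]
        sp["bmi_kg_m2_per_year"] = [bmi, 0.01]
        sp["diabetes_onset"] = 0.0
        sp["bpmed_start"] = 0.0
        sp["smoking_start"] = 0.0
        sp["smoking_quit"] = 0.0
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
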