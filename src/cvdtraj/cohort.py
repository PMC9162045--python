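"""Synthetic longitudinal cohort generator.

Emulates the structure of a prospective population-based aging cohort
sampled in 5-year waves (T1..T6): entry ages 35-80 on a 5-year grid, a
three-component mixture of cardiovascular-risk trajectories (accelerated /
average / stable) that share baseline risk-factor distributions and differ
only in their slopes, discrete-time multistate transitions
(healthy -> AD | VaD | death, dementia -> death) concentrated in older
subjects, outcome-dependent wave dropout (nonignorable), item-level MAR
covariate gaps, and an episodic-memory composite with age-related decline
and excess decline in the accelerated component.

Two tables come out of :func:`generate_cohort`: the long-format cohort
(one row per subject-wave) and a ground-truth table (``SimTruth``) keyed by
subject, which downstream recovery tests compare against.  Missingness is
applied afterwards by :func:`apply_missingness` and never touches the
truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "generate_cohort",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

CLASSES = ("accelerated", "average", "stable")
STATES = ("healthy", "AD", "VaD", "dead", "dropped")

#: fixed long-format column order (the on-disk CSV dialect)
COHORT_COLUMNS = [
    "subject_id",
    "wave_index",
    "age",
    "sex",
    "education_years",
    "apoe4",
    "sbp_mmHg",
    "bp_medication",
    "bmi_kg_m2",
    "smoker",
    "diabetes",
    "em_task1",
    "em_task2",
    "em_task3",
    "em_task4",
    "em_task5",
    "em_composite",
    "state",
]

#: risk-factor covariates subject to item-level missingness
FRS_COVARIATES = ["sbp_mmHg", "bp_medication", "bmi_kg_m2", "smoker", "diabetes"]

_EM_TASK_WEIGHTS = np.array([16.0, 16.0, 16.0, 16.0, 12.0]) / 76.0


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _default_slope_params():
    # Annual drifts of the continuous risk factors and per-wave incidences
    # of the binary ones, per trajectory class.  The study reports no
    # per-class slope magnitudes, so these are calibrated to produce
    # clearly separated risk trajectories from shared baselines.
    return {
        "accelerated": {
            "sbp_mmHg_per_year": [2.2, 0.40],
            "bmi_kg_m2_per_year": [0.16, 0.04],
            "diabetes_onset": 0.040,
            "bpmed_start": 0.10,
            "smoking_start": 0.010,
            "smoking_quit": 0.05,
        },
        "average": {
            "sbp_mmHg_per_year": [0.8, 0.30],
            "bmi_kg_m2_per_year": [0.05, 0.03],
            "diabetes_onset": 0.010,
            "bpmed_start": 0.05,
            "smoking_start": 0.005,
            "smoking_quit": 0.08,
        },
        "stable": {
            "sbp_mmHg_per_year": [0.0, 0.25],
            "bmi_kg_m2_per_year": [0.0, 0.02],
            "diabetes_onset": 0.004,
            "bpmed_start": 0.02,
            "smoking_start": 0.005,
            "smoking_quit": 0.10,
        },
    }


def _default_baselines():
    return {
        "male": {
            "sbp_mmHg": [128.0, 15.0],
            "bmi_kg_m2": [26.0, 3.5],
            "smoker": 0.22,
            "diabetes": 0.05,
            "bp_medication": 0.10,
        },
        "female": {
            "sbp_mmHg": [124.0, 16.0],
            "bmi_kg_m2": [25.5, 4.2],
            "smoker": 0.26,
            "diabetes": 0.04,
            "bp_medication": 0.10,
        },
        "education_years": [10.5, 3.8],
    }


def _default_hazards():
    # Per-wave conditional transition probabilities for the reference cell
    # (stable class, age < 70, APOE e4 noncarrier) with multiplicative
    # effects of class, old age, and APOE e4 (on AD only).
    return {
        "healthy->AD": {
            "base": 0.003,
            "class": {"accelerated": 3.5, "average": 2.0, "stable": 1.0},
            "age70": 10.0,
            "apoe4": 3.0,
        },
        "healthy->VaD": {
            "base": 0.002,
            "class": {"accelerated": 3.5, "average": 2.0, "stable": 1.0},
            "age70": 10.0,
            "apoe4": 1.0,
        },
        "healthy->death": {
            "base": 0.008,
            "class": {"accelerated": 1.5, "average": 1.2, "stable": 1.0},
            "age70": 10.0,
            "apoe4": 1.0,
        },
        "dementia->death": {
            "base": 0.15,
            "class": {"accelerated": 1.0, "average": 1.0, "stable": 1.0},
            "age70": 1.5,
            "apoe4": 1.0,
        },
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 1244
    n_waves: int = 6
    wave_spacing_years: float = 5.0
    entry_age_range: tuple[float, float] = (35.0, 80.0)
    trajectory_mixture: dict = field(
        default_factory=lambda: {"accelerated": 0.18, "average": 0.60, "stable": 0.22}
    )
    slope_params: dict = field(default_factory=_default_slope_params)
    baseline_covariate_distributions: dict = field(default_factory=_default_baselines)
    apoe4_prevalence: float = 0.31
    hazard_params: dict = field(default_factory=_default_hazards)
    #: minimum age (at the event wave) for a dementia event; None disables
    dementia_age_floor: float | None = 65.0
    #: per-wave dropout probability conditional on being at risk, plus a
    #: log-multiplier applied to subjects with a later latent dementia or
    #: death event (the nonignorable mechanism).  The marginal per-wave
    #: rate is preserved exactly in expectation.
    dropout_hazard: dict = field(
        default_factory=lambda: {
            "per_wave": {3: 0.015, 4: 0.06, 5: 0.30, 6: 0.39},
            "outcome_coef": 0.7,
        }
    )
    #: per-covariate base MAR probability; realized probability depends
    #: only on observed age and sex
    missingness_rate: dict = field(
        default_factory=lambda: {
            "sbp_mmHg": 0.06,
            "bmi_kg_m2": 0.06,
            "smoker": 0.03,
            "diabetes": 0.02,
            "bp_medication": 0.03,
        }
    )
    #: wave-to-wave measurement noise on the continuous risk factors
    measurement_noise_sd: dict = field(
        default_factory=lambda: {"sbp_mmHg": 4.0, "bmi_kg_m2": 0.6}
    )
    em_params: dict = field(
        default_factory=lambda: {
            "baseline_mean": 36.0,
            "baseline_sd": 11.0,
            "age_slope_per_year": -0.30,
            # between-subject SD of the individual decline rate: memory
            # trajectories vary markedly across people of the same age
            "slope_sd_per_year": 0.6,
            "accelerated_excess_per_year": -0.30,
            "dementia_drop": -6.0,
            "noise_sd": 3.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_waves < 2:
            raise ConfigError("n_waves: must be >= 2")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects: must be positive")
        mix = self.trajectory_mixture
        if set(mix) != set(CLASSES):
            raise ConfigError(f"trajectory_mixture: keys must be {CLASSES}")
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ConfigError("trajectory_mixture: proportions must sum to 1")
        if any(p < 0 for p in mix.values()):
            raise ConfigError("trajectory_mixture: proportions must be >= 0")
        if not 0.0 <= self.apoe4_prevalence <= 1.0:
            raise ConfigError("apoe4_prevalence: must be in [0, 1]")
        for name, tr in self.hazard_params.items():
            if not 0.0 <= tr["base"] <= 1.0:
                raise ConfigError(f"hazard_params[{name}].base: must be in [0, 1]")
        for w, p in self.dropout_hazard["per_wave"].items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"dropout_hazard.per_wave[{w}]: must be in [0, 1]")
        for v, p in self.missingness_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"missingness_rate[{v}]: must be in [0, 1]")

    # -- convenience constructors used by calibration studies/tests ------

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def null(cls, **kw) -> "GeneratorConfig":
        """Config with no class, age, or APOE effects on any hazard and
        identical covariate slopes across classes (covariate-free events).
        """
        cfg = cls(**kw)
        for tr in cfg.hazard_params.values():
            tr["class"] = {c: 1.0 for c in CLASSES}
            tr["age70"] = 1.0
            tr["apoe4"] = 1.0
        avg = cfg.slope_params["average"]
        cfg.slope_params = {c: dict(avg) for c in CLASSES}
        cfg.dementia_age_floor = None
        return cfg


def _hazard_for(tr: dict, classes, age_now, apoe_carrier) -> np.ndarray:
    mult = np.array([tr["class"][c] for c in classes])
    mult = mult * np.where(age_now >= 70.0, tr["age70"], 1.0)
    mult = mult * np.where(apoe_carrier, tr["apoe4"], 1.0)
    return np.clip(tr["base"] * mult, 0.0, 1.0)


def _split_em_tasks(composite: np.ndarray) -> np.ndarray:
    """Split composites into 5 task scores whose sum is exact."""
    tasks = composite[:, None] * _EM_TASK_WEIGHTS[None, :]
    tasks[:, 4] = composite - tasks[:, :4].sum(axis=1)
    return tasks


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a complete latent cohort (no dropout, no item missingness).

    Returns ``(cohort, truth)``: the long-format subject-wave table and the
    per-subject ground-truth table.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    W = config.n_waves
    dt = config.wave_spacing_years

    # ---- per-subject baseline draws -----------------------------------
    lo, hi = config.entry_age_range
    grid = np.arange(lo, hi + 1e-9, 5.0)
    entry_age = rng.choice(grid, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    apoe = rng.random(n) < config.apoe4_prevalence
    probs = [config.trajectory_mixture[c] for c in CLASSES]
    true_class = rng.choice(np.array(CLASSES), size=n, p=probs)

    bl = config.baseline_covariate_distributions
    edu = np.clip(
        rng.normal(bl["education_years"][0], bl["education_years"][1], n), 0.0, None
    )
    sbp0 = np.empty(n)
    bmi0 = np.empty(n)
    smoker0 = np.empty(n, dtype=bool)
    diab0 = np.empty(n, dtype=bool)
    med0 = np.empty(n, dtype=bool)
    for s in ("male", "female"):
        m = sex == s
        k = bl[s]
        sbp0[m] = rng.normal(k["sbp_mmHg"][0], k["sbp_mmHg"][1], m.sum())
        bmi0[m] = rng.normal(k["bmi_kg_m2"][0], k["bmi_kg_m2"][1], m.sum())
        smoker0[m] = rng.random(m.sum()) < k["smoker"]
        diab0[m] = rng.random(m.sum()) < k["diabetes"]
        med0[m] = rng.random(m.sum()) < k["bp_medication"]
    sbp0 = np.clip(sbp0, 85.0, None)
    bmi0 = np.clip(bmi0, 16.0, None)

    sp = config.slope_params
    sbp_slope = np.empty(n)
    bmi_slope = np.empty(n)
    for c in CLASSES:
        m = true_class == c
        mu, sd = sp[c]["sbp_mmHg_per_year"]
        sbp_slope[m] = rng.normal(mu, sd, m.sum())
        mu, sd = sp[c]["bmi_kg_m2_per_year"]
        bmi_slope[m] = rng.normal(mu, sd, m.sum())

    # ---- covariate paths ----------------------------------------------
    years = np.arange(W) * dt
    noise = config.measurement_noise_sd
    sbp = sbp0[:, None] + sbp_slope[:, None] * years[None, :]
    bmi = bmi0[:, None] + bmi_slope[:, None] * years[None, :]
    if noise.get("sbp_mmHg", 0.0) > 0:
        sbp = sbp + rng.normal(0.0, noise["sbp_mmHg"], (n, W))
    if noise.get("bmi_kg_m2", 0.0) > 0:
        bmi = bmi + rng.normal(0.0, noise["bmi_kg_m2"], (n, W))
    sbp = np.clip(sbp, 80.0, None)
    bmi = np.clip(bmi, 15.0, None)

    smoker = np.empty((n, W), dtype=bool)
    diab = np.empty((n, W), dtype=bool)
    med = np.empty((n, W), dtype=bool)
    smoker[:, 0], diab[:, 0], med[:, 0] = smoker0, diab0, med0
    p_start = np.empty(n)
    p_quit = np.empty(n)
    p_diab = np.empty(n)
    p_med = np.empty(n)
    for c in CLASSES:
        m = true_class == c
        p_start[m] = sp[c]["smoking_start"]
        p_quit[m] = sp[c]["smoking_quit"]
        p_diab[m] = sp[c]["diabetes_onset"]
        p_med[m] = sp[c]["bpmed_start"]
    for w in range(1, W):
        u = rng.random((n, 3))
        smoker[:, w] = np.where(
            smoker[:, w - 1], u[:, 0] >= p_quit, u[:, 0] < p_start
        )
        diab[:, w] = diab[:, w - 1] | (u[:, 1] < p_diab)
        med[:, w] = med[:, w - 1] | (u[:, 2] < p_med)

    # ---- multistate transitions (discrete per-wave hazards) -----------
    hz = config.hazard_params
    state = np.zeros((n, W), dtype=np.int8)  # 0 healthy, 1 AD, 2 VaD, 3 dead
    dem_wave = np.full(n, np.nan)
    dem_type = np.full(n, "", dtype=object)
    death_wave = np.full(n, np.nan)
    for w in range(1, W):
        age_now = entry_age + (w - 1) * dt
        age_next = entry_age + w * dt
        prev = state[:, w - 1]
        state[:, w] = prev
        healthy = prev == 0
        if healthy.any():
            h_ad = _hazard_for(hz["healthy->AD"], true_class, age_now, apoe)
            h_vad = _hazard_for(hz["healthy->VaD"], true_class, age_now, apoe)
            h_die = _hazard_for(hz["healthy->death"], true_class, age_now, apoe)
            if config.dementia_age_floor is not None:
                young = age_next <= config.dementia_age_floor
                h_ad = np.where(young, 0.0, h_ad)
                h_vad = np.where(young, 0.0, h_vad)
            total = h_ad + h_vad + h_die
            if np.any(total > 1.0):
                raise ConfigError(
                    "hazard_params: summed per-wave exit probability exceeds 1"
                )
            u = rng.random(n)
            to_ad = healthy & (u < h_ad)
            to_vad = healthy & ~to_ad & (u < h_ad + h_vad)
            to_die = healthy & ~to_ad & ~to_vad & (u < total)
            state[to_ad, w] = 1
            state[to_vad, w] = 2
            state[to_die, w] = 3
            dem_wave[to_ad | to_vad] = w + 1  # wave_index is 1-based
            dem_type[to_ad] = "AD"
            dem_type[to_vad] = "VaD"
            death_wave[to_die] = w + 1
        dem = (prev == 1) | (prev == 2)
        if dem.any():
            h = _hazard_for(hz["dementia->death"], true_class, age_now, apoe)
            dies = dem & (rng.random(n) < h)
            state[dies, w] = 3
            death_wave[dies] = w + 1

    # ---- episodic memory ----------------------------------------------
    em = config.em_params
    intercept = rng.normal(em["baseline_mean"], em["baseline_sd"], n)
    excess = np.where(true_class == "accelerated", em["accelerated_excess_per_year"], 0.0)
    indiv_slope = rng.normal(0.0, em.get("slope_sd_per_year", 0.0), n)
    age_mat = entry_age[:, None] + years[None, :]
    comp = (
        intercept[:, None]
        + em["age_slope_per_year"] * (age_mat - 60.0)
        + (excess + indiv_slope)[:, None] * years[None, :]
        + rng.normal(0.0, em["noise_sd"], (n, W))
    )
    comp = comp + np.where(state >= 1, em["dementia_drop"], 0.0) * (state < 3)
    comp = np.clip(comp, 0.0, 76.0)

    # ---- assemble long table ------------------------------------------
    state_names = np.array(["healthy", "AD", "VaD", "dead"])
    rows = {
        "subject_id": np.repeat(np.arange(1, n + 1), W),
        "wave_index": np.tile(np.arange(1, W + 1), n),
        "age": age_mat.ravel(),
        "sex": np.repeat(sex, W),
        "education_years": np.repeat(np.round(edu, 3), W),
        "apoe4": np.repeat(np.where(apoe, "carrier", "noncarrier"), W),
        "sbp_mmHg": np.round(sbp, 3).ravel(),
        "bp_medication": med.astype(float).ravel(),
        "bmi_kg_m2": np.round(bmi, 3).ravel(),
        "smoker": smoker.astype(float).ravel(),
        "diabetes": diab.astype(float).ravel(),
        "state": state_names[state.ravel()],
    }
    tasks = _split_em_tasks(np.round(comp, 3).ravel())
    for j in range(5):
        rows[f"em_task{j + 1}"] = tasks[:, j]
    rows["em_composite"] = np.round(comp, 3).ravel()
    cohort = pd.DataFrame(rows)[COHORT_COLUMNS]

    # the dead are not measured
    dead = cohort["state"] == "dead"
    meas_cols = FRS_COVARIATES + [f"em_task{j}" for j in range(1, 6)] + ["em_composite"]
    cohort.loc[dead, meas_cols] = np.nan

    truth = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "true_class": true_class,
            "entry_age": entry_age,
            "sbp_slope_per_year": sbp_slope,
            "bmi_slope_per_year": bmi_slope,
            "em_excess_per_year": excess,
            "dementia_wave": dem_wave,
            "dementia_type": dem_type,
            "death_wave": death_wave,
            "dropout_wave": np.full(n, np.nan),
        }
    )
    for name in hz:
        col = "hazmult_" + name.replace("healthy->", "h_").replace(
            "dementia->", "d_"
        )
        tr = hz[name]
        truth[col] = np.array([tr["class"][c] for c in true_class])
    return cohort, truth


def apply_missingness(
    cohort: pd.DataFrame, config: GeneratorConfig, truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Apply wave dropout (nonignorable) and item-level MAR masking.

    Dropout at wave *w* means the subject does not attend wave *w* or any
    later wave: those rows get state ``dropped`` and all measured columns
    blank.  Subjects with a later latent dementia or death event drop out
    at ``exp(outcome_coef)`` times the rate of the rest, with the marginal
    per-wave rate preserved in expectation (so the configured per-wave
    rates remain the realized ones).  Item-level masking probability
    depends only on observed age and sex (MAR).

    Returns ``(observed_cohort, truth)``; if ``truth`` is given, it is
    returned with ``dropout_wave`` filled in, otherwise None.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    df = cohort.copy()
    n = df["subject_id"].nunique()
    W = int(df["wave_index"].max())
    wide_state = (
        df.pivot(index="subject_id", columns="wave_index", values="state")
        .reindex(columns=range(1, W + 1))
    )
    sids = wide_state.index.to_numpy()
    smat = wide_state.to_numpy()

    # latent "on a path to dementia/death" indicator per subject and wave:
    # any dementia or death state at a strictly later wave
    bad = np.isin(smat, ("AD", "VaD", "dead"))
    later_bad = np.zeros_like(bad)
    for w in range(W - 2, -1, -1):
        later_bad[:, w] = bad[:, w + 1] | later_bad[:, w + 1]

    coef = float(config.dropout_hazard.get("outcome_coef", 0.0))
    mult = np.exp(coef)
    dropped = np.zeros(n, dtype=bool)
    dropout_wave = np.full(n, np.nan)
    for w, p in sorted(config.dropout_hazard["per_wave"].items()):
        wi = int(w) - 1
        if wi >= W or p <= 0:
            continue
        alive = smat[:, wi] != "dead"
        at_risk = alive & ~dropped
        if not at_risk.any():
            continue
        doomed = later_bad[:, wi] | np.isin(smat[:, wi], ("AD", "VaD"))
        f = doomed[at_risk].mean()
        p_other = p / (1.0 - f + f * mult)
        p_sub = np.where(doomed, np.minimum(mult * p_other, 1.0), p_other)
        hit = at_risk & (rng.random(n) < p_sub)
        dropped |= hit
        dropout_wave[hit] = int(w)

    # write dropout into the long table
    drop_map = pd.Series(dropout_wave, index=sids)
    dw = df["subject_id"].map(drop_map).to_numpy()
    is_dropped = ~np.isnan(dw) & (df["wave_index"].to_numpy() >= dw)
    meas_cols = FRS_COVARIATES + [f"em_task{j}" for j in range(1, 6)] + ["em_composite"]
    df.loc[is_dropped, meas_cols] = np.nan
    df.loc[is_dropped, "state"] = "dropped"

    # item-level MAR masking on attended, alive rows
    attended = ~is_dropped & (df["state"] != "dead")
    age = df["age"].to_numpy()
    female = (df["sex"] == "female").to_numpy()
    mar_scale = (1.0 + 0.5 * (age >= 70.0)) * (1.0 + 0.2 * female)
    for var, base in config.missingness_rate.items():
        if base <= 0:
            continue
        pmask = np.clip(base * mar_scale, 0.0, 0.95)
        hit = attended & (rng.random(len(df)) < pmask)
        df.loc[hit, var] = np.nan

    if truth is not None:
        truth = truth.copy()
        truth["dropout_wave"] = truth["subject_id"].map(drop_map).to_numpy()
    return df, truth


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write the long-format cohort CSV (missing entries as empty fields)."""
    df.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS + [c for c in df.columns if c not in COHORT_COLUMNS]]
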