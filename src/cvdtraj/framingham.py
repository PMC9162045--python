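"""Office-based Framingham general-CVD 10-year risk.

The office-based (non-laboratory) variant of the general cardiovascular
disease risk function replaces the lipid panel with body-mass index, so a
risk probability can be computed from a routine health examination alone:
age, sex, systolic blood pressure (with separate coefficients by
antihypertensive-treatment status), BMI, current smoking, and diabetes.

The sex-specific Cox coefficients, baseline 10-year survival ``s0`` and
mean linear predictor are shipped as a versioned JSON constants file
(``data/framingham_office_bmi.json``) rather than hard-coded, so alternate
calibrations can be swapped in.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FrsProfile",
    "FrsSeries",
    "load_risk_constants",
    "frs_risk",
    "frs_risk_vector",
    "build_frs_series",
    "group_by_cutoffs",
]

# Ages outside the derivation range of the risk function are allowed but
# flagged once per process.
_DERIVATION_AGE_RANGE = (30.0, 74.0)


@dataclass(frozen=True)
class FrsProfile:
    """One wave's office-based risk-factor profile."""

    age: float
    sex: str  # "male" | "female"
    sbp_mmHg: float
    bp_medication: bool
    bmi_kg_m2: float
    smoker: bool
    diabetes: bool

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sbp_mmHg <= 0:
            raise ValueError(f"sbp_mmHg must be positive, got {self.sbp_mmHg}")
        if self.bmi_kg_m2 <= 0:
            raise ValueError(f"bmi_kg_m2 must be positive, got {self.bmi_kg_m2}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class FrsSeries:
    """Per-wave 10-year risk probabilities for one subject.

    Waves at or after ``censor_wave`` (the first wave at/after a dementia
    diagnosis) carry no risk value: only pre-diagnosis scores enter the
    trajectory analysis.
    """

    subject_id: object
    waves: tuple[int, ...]
    years: tuple[float, ...]  # years since the subject's first wave
    risks: tuple[float, ...]
    censor_wave: int | None = None
    baseline_age: float | None = None  # age at the subject's first wave

    def __post_init__(self) -> None:
        if self.censor_wave is not None and any(
            w >= self.censor_wave for w in self.waves
        ):
            raise ValueError("FrsSeries contains waves at/after censor_wave")
        if any(not (0.0 < r < 1.0) for r in self.risks):
            raise ValueError("risks must lie strictly within (0, 1)")

    def __len__(self) -> int:
        return len(self.waves)


def load_risk_constants(path: str | None = None) -> dict:
    """Load the risk-function constants (default: the shipped file)."""
    if path is not None:
        with open(path) as fh:
            return json.load(fh)
    ref = resources.files("cvdtraj").joinpath("data/framingham_office_bmi.json")
    return json.loads(ref.read_text())


def frs_risk_vector(
    age,
    sex,
    sbp_mmHg,
    bp_medication,
    bmi_kg_m2,
    smoker,
    diabetes,
    constants: dict | None = None,
):
    """Vectorized 10-year general-CVD risk, ``1 - s0**exp(lp - lp_mean)``.

    All arguments broadcast; ``sex`` is an array of "male"/"female".
    Returns probabilities strictly inside (0, 1).
    """
    c = constants if constants is not None else load_risk_constants()
    age = np.atleast_1d(np.asarray(age, dtype=float))
    sbp = np.atleast_1d(np.asarray(sbp_mmHg, dtype=float))
    bmi = np.atleast_1d(np.asarray(bmi_kg_m2, dtype=float))
    sexarr = np.atleast_1d(np.asarray(sex))
    treated = np.atleast_1d(np.asarray(bp_medication, dtype=bool))
    smk = np.atleast_1d(np.asarray(smoker, dtype=float))
    dia = np.atleast_1d(np.asarray(diabetes, dtype=float))
    age, sbp, bmi, sexarr, treated, smk, dia = np.broadcast_arrays(
        age, sbp, bmi, sexarr, treated, smk, dia
    )
    if np.any(age <= 0) or np.any(sbp <= 0) or np.any(bmi <= 0):
        raise ValueError("age, SBP, and BMI must all be positive")
    if np.any(age < _DERIVATION_AGE_RANGE[0]) or np.any(age > _DERIVATION_AGE_RANGE[1]):
        warnings.warn(
            "FRS evaluated outside the 30-74 derivation age range; "
            "no capping is applied",
            stacklevel=2,
        )
    is_male = sexarr == "male"
    risk = np.empty(age.shape, dtype=float)
    for sexname, mask in (("male", is_male), ("female", ~is_male)):
        if not np.any(mask):
            continue
        k = c[sexname]
        b_sbp = np.where(treated, k["b_ln_sbp_treated"], k["b_ln_sbp_untreated"])
        lp = (
            k["b_ln_age"] * np.log(age)
            + k["b_ln_bmi"] * np.log(bmi)
            + b_sbp * np.log(sbp)
            + k["b_smoker"] * smk
            + k["b_diabetes"] * dia
        )
        risk[mask] = 1.0 - k["s0"] ** np.exp(lp[mask] - k["lp_mean"])
    return risk


def frs_risk(profile: FrsProfile, constants: dict | None = None) -> float:
    """10-year general-CVD risk for one complete profile."""
    return float(
        frs_risk_vector(
            profile.age,
            profile.sex,
            profile.sbp_mmHg,
            profile.bp_medication,
            profile.bmi_kg_m2,
            profile.smoker,
            profile.diabetes,
            constants,
        )[0]
    )


def build_frs_series(
    subject_rows: pd.DataFrame,
    wave_spacing_years: float = 5.0,
    constants: dict | None = None,
) -> FrsSeries:
    """Per-wave risk series for one subject's long-format rows.

    Only pre-diagnosis waves contribute: the first wave whose state is a
    dementia state (AD/VaD) censors the series from there on.  Waves with
    any missing risk-factor covariate are skipped (they are imputed
    upstream in the full pipeline).  A series may be empty; classification
    then marks the subject unclassified.
    """
    rows = subject_rows.sort_values("wave_index")
    sid = rows["subject_id"].iloc[0]
    dementia = rows["state"].isin(["AD", "VaD"])
    censor_wave = int(rows.loc[dementia, "wave_index"].min()) if dementia.any() else None

    needed = ["age", "sex", "sbp_mmHg", "bp_medication", "bmi_kg_m2", "smoker", "diabetes"]
    waves, years, risks = [], [], []
    first_wave = int(rows["wave_index"].min())
    for _, r in rows.iterrows():
        w = int(r["wave_index"])
        if censor_wave is not None and w >= censor_wave:
            continue
        if r["state"] not in ("healthy",):
            continue
        if any(pd.isna(r[col]) for col in needed):
            continue
        risk = frs_risk_vector(
            r["age"], r["sex"], r["sbp_mmHg"], bool(r["bp_medication"]),
            r["bmi_kg_m2"], bool(r["smoker"]), bool(r["diabetes"]), constants,
        )[0]
        waves.append(w)
        years.append((w - first_wave) * wave_spacing_years)
        risks.append(float(risk))
    return FrsSeries(
        subject_id=sid,
        waves=tuple(waves),
        years=tuple(years),
        risks=tuple(risks),
        censor_wave=censor_wave,
        baseline_age=float(rows["age"].iloc[0]),
    )


def group_by_cutoffs(risks, cutpoints: tuple[float, float] = (0.06, 0.20)) -> np.ndarray:
    """Bin reference-wave risks into low (<6%), medium (6-20%), high (>20%).

    Both cut values belong to the medium bin, matching the conventional
    "<6%, 6% to 20%, >20%" reading.
    """
    lo, hi = cutpoints
    r = np.atleast_1d(np.asarray(risks, dtype=float))
    out = np.where(r < lo, "low", np.where(r > hi, "high", "medium"))
    return out
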