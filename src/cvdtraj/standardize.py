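"""Bayesian regression standardization (g-computation) over BART fits.

BART predicts but does not produce coefficients, so marginal association
measures are obtained by standardization: for each retained posterior
draw, pseudodata are resampled from the empirical joint distribution of
the baseline confounders (age, sex, education, APOE e4), every pseudo-row
is assigned the same fixed exposure group, the multistate curves are
computed per row and averaged -- one standardized curve per draw.  The
group-standardized curves are then contrasted draw-by-draw into risk
ratios RR(t) with equal-tailed credible intervals, the absolute risk
reduction (ARR, an incidence difference at a reference wave), and the
number needed to treat (NNT, the reciprocal of the ARR rounded to the
nearest integer).

Subgroup standardization (e.g. APOE e4 carriers only) conditions the
pseudodata source on that covariate instead of marginalizing over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multistate import occupation_curves

__all__ = [
    "StandardizationConfig",
    "StandardizedCurve",
    "EffectSummary",
    "sample_pseudodata",
    "standardized_curves",
    "risk_ratio",
    "arr_nnt",
    "write_rr_table",
]


@dataclass
class StandardizationConfig:
    pseudodata_size: int = 10_000
    n_curve_draws: int = 1_000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudodata_size < 1 or self.n_curve_draws < 1:
            raise ValueError("pseudodata_size and n_curve_draws must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class StandardizedCurve:
    """Group-standardized curves: per-draw, per-wave quantities."""

    group: str
    waves: np.ndarray  # wave indices, 1-based
    incidence: np.ndarray  # (n_draws, n_waves) cumulative incidence, target state
    occupancy: dict = field(default_factory=dict)  # state -> (n_draws, n_waves)

    def __post_init__(self) -> None:
        inc = self.incidence
        if np.any(inc < -1e-9) or np.any(inc > 1.0 + 1e-9):
            raise ValueError("incidence values outside [0, 1]")
        if np.any(np.diff(inc, axis=1) < -1e-9):
            raise ValueError("cumulative incidence must be nondecreasing per draw")

    @property
    def mean(self) -> np.ndarray:
        return self.incidence.mean(axis=0)


@dataclass
class EffectSummary:
    contrast: str
    waves: np.ndarray
    rr_mean: np.ndarray
    rr_ci_low: np.ndarray
    rr_ci_high: np.ndarray
    arr: float | None = None
    nnt: int | None = None
    reference_wave: int | None = None


def sample_pseudodata(
    baseline: pd.DataFrame,
    size: int,
    seed: int | np.random.Generator = 0,
    condition: dict | None = None,
) -> pd.DataFrame:
    """Resample baseline-confounder rows with replacement.

    Row-wise resampling preserves the joint dependence among confounders.
    ``condition`` (column -> value) restricts the source rows, which is
    how subgroup standardization conditions on a covariate.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    src = baseline
    if condition:
        for col, val in condition.items():
            src = src[src[col] == val]
        if len(src) == 0:
            raise ValueError(f"no source rows satisfy condition {condition}")
    idx = rng.integers(0, len(src), size=size)
    return src.iloc[idx].reset_index(drop=True)


def standardized_curves(
    posteriors: dict,
    pseudodata: pd.DataFrame,
    group: str,
    group_codes: dict,
    target_state: str = "dementia",
    n_waves: int = 6,
    model: str = "illness-death",
    n_curve_draws: int | None = None,
) -> StandardizedCurve:
    """One standardized cumulative-incidence curve per posterior draw.

    Every pseudodata row's exposure is set to ``group`` (the grouping is
    treated as fixed), curves are computed per row for each retained draw
    and averaged over rows.  When ``n_curve_draws`` is smaller than the
    stored posterior, an evenly spaced subset of draws is used -- the same
    subset for every group, so contrasts stay paired by draw.
    """
    profiles = pseudodata.copy()
    profiles["group_code"] = float(group_codes[group])
    total = next(iter(posteriors.values())).n_draws
    draw_idx = None
    if n_curve_draws is not None and n_curve_draws < total:
        draw_idx = np.linspace(0, total - 1, n_curve_draws).astype(int)
    curves = occupation_curves(
        posteriors, profiles, n_waves=n_waves, model=model,
        average_rows=True, draw_indices=draw_idx,
    )
    key = f"cuminc_{target_state}" if f"cuminc_{target_state}" in curves else target_state
    return StandardizedCurve(
        group=group,
        waves=np.arange(1, n_waves + 1),
        incidence=curves[key],
        occupancy=curves,
    )


def risk_ratio(
    curve_num: StandardizedCurve,
    curve_den: StandardizedCurve,
    ci_level: float = 0.95,
    min_waves: int = 2,
) -> EffectSummary:
    """Draw-wise RR(t) = incidence_num(t) / incidence_den(t), summarized.

    Curves must share wave grid and draw count (paired by draw).  Waves
    before ``min_waves`` (incidence identically zero at T1) and draws with
    zero denominator are reported as missing, never as infinity.
    """
    a, b = curve_num.incidence, curve_den.incidence
    if a.shape != b.shape:
        raise ValueError("curves must share wave grid and draw count")
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.nan)
    waves = curve_num.waves
    keep = waves >= min_waves
    lo = (1.0 - ci_level) / 2.0
    mean = np.full(waves.shape, np.nan)
    ci_l = np.full(waves.shape, np.nan)
    ci_h = np.full(waves.shape, np.nan)
    for j in np.flatnonzero(keep):
        col = rr[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        mean[j] = col.mean()
        ci_l[j], ci_h[j] = np.quantile(col, [lo, 1.0 - lo])
    return EffectSummary(
        contrast=f"{curve_num.group} vs {curve_den.group}",
        waves=waves,
        rr_mean=mean,
        rr_ci_low=ci_l,
        rr_ci_high=ci_h,
    )


def arr_nnt(
    curve_low: StandardizedCurve,
    curve_high: StandardizedCurve,
    reference_wave: int | None = None,
) -> tuple[float, int | None]:
    """Absolute risk reduction and number needed to treat.

    ARR = posterior-mean incidence(high-risk group) minus posterior-mean
    incidence(low-risk group) at the reference wave (default: the final
    wave); NNT is the nearest integer to 1/ARR, or None when ARR <= 0.
    """
    waves = curve_low.waves
    if reference_wave is None:
        reference_wave = int(waves[-1])
    j = int(np.flatnonzero(waves == reference_wave)[0])
    arr = float(curve_high.mean[j] - curve_low.mean[j])
    nnt = int(round(1.0 / arr)) if arr > 0 else None
    return arr, nnt


def write_rr_table(summaries: list[EffectSummary], path) -> pd.DataFrame:
    """Tidy CSV of (contrast, wave, RR_mean, CI_low, CI_high)."""
    rows = []
    for s in summaries:
        for j, w in enumerate(s.waves):
            rows.append(
                {
                    "contrast": s.contrast,
                    "wave": int(w),
                    "RR_mean": s.rr_mean[j],
                    "CI_low": s.rr_ci_low[j],
                    "CI_high": s.rr_ci_high[j],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_effect_json(summaries: list[EffectSummary], path) -> None:
    payload = {}
    for s in summaries:
        payload[s.contrast] = {
            "ARR": s.arr,
            "NNT": s.nnt,
            "reference_wave": s.reference_wave,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
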