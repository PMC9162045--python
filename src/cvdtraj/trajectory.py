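"""Cardiovascular-risk trajectory classification.

Each subject's 10-year-risk series (pre-diagnosis waves only) is reduced to
an ordinary least-squares slope against years since baseline.  Because risk
grows mechanically with age and with the level already reached, raw slopes
are residualized on baseline age and baseline risk across subjects; the
residual ("adjusted") slopes are what get classified.

Dropout in an aging cohort is nonignorable: subjects on a path to dementia
or death leave earlier and have steeper risk growth.  The population slope
mean and SD are therefore estimated with a pattern-mixture decomposition -
stratify on dropout pattern (last observed wave), average within patterns,
and recombine with pattern frequencies as weights (law of total variance
for the SD).  Subjects are then labelled *accelerated* if their adjusted
slope lies strictly more than ``sd_threshold`` SDs above the mean,
*stable* if strictly more than ``sd_threshold`` SDs below, *average*
otherwise; subjects with fewer than ``min_waves`` usable risk values stay
*unclassified*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .framingham import FrsSeries, build_frs_series

__all__ = [
    "TrajectoryConfig",
    "fit_subject_slope",
    "pattern_mixture_moments",
    "classify",
    "TrajectoryClassifier",
    "label_cohort",
]


@dataclass
class TrajectoryConfig:
    sd_threshold: float = 1.0
    min_waves: int = 2
    adjust_for: tuple[str, ...] = ("baseline_age", "baseline_frs")

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.min_waves < 2:
            raise ValueError("min_waves must be >= 2")


def fit_subject_slope(series: FrsSeries, min_waves: int = 2) -> float:
    """OLS slope of risk against years since the subject's first wave.

    Returns ``nan`` (the unclassified marker) when fewer than ``min_waves``
    points are available.
    """
    if len(series) < min_waves:
        return float("nan")
    t = np.asarray(series.years, dtype=float)
    r = np.asarray(series.risks, dtype=float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom == 0.0:
        return float("nan")
    return float((tc * (r - r.mean())).sum() / denom)


def pattern_mixture_moments(
    slopes, patterns, weights: dict | None = None
) -> tuple[float, float]:
    """Population mean and SD of slopes under pattern-mixture weighting.

    ``patterns`` is the per-subject dropout pattern (last observed wave).
    The population mean is the pattern-frequency-weighted mean of the
    within-pattern means; the population variance combines within- and
    between-pattern variance (law of total variance).  With a single
    pattern this reduces exactly to the plain mean/SD.
    """
    s = np.asarray(slopes, dtype=float)
    p = np.asarray(patterns)
    ok = ~np.isnan(s)
    s, p = s[ok], p[ok]
    if s.size == 0:
        raise ValueError("no classifiable subjects (all slopes missing)")
    pats, inv = np.unique(p, return_inverse=True)
    if weights is None:
        w = np.bincount(inv).astype(float)
        w /= w.sum()
    else:
        w = np.array([weights[k] for k in pats], dtype=float)
        w /= w.sum()
    means = np.array([s[inv == i].mean() for i in range(len(pats))])
    vars_ = np.array([s[inv == i].var(ddof=0) for i in range(len(pats))])
    mu = float((w * means).sum())
    var = float((w * vars_).sum() + (w * (means - mu) ** 2).sum())
    return mu, float(np.sqrt(var))


def classify(
    adjusted_slopes, mean: float, sd: float, sd_threshold: float = 1.0
) -> np.ndarray:
    """Label slopes: strictly beyond ``mean ± sd_threshold*sd`` -> tail class."""
    s = np.asarray(adjusted_slopes, dtype=float)
    out = np.full(s.shape, "average", dtype=object)
    if sd > 0:
        out[s > mean + sd_threshold * sd] = "accelerated"
        out[s < mean - sd_threshold * sd] = "stable"
    out[np.isnan(s)] = "unclassified"
    return out


class TrajectoryClassifier(BaseEstimator):
    """Slope-based trajectory classifier over per-subject risk series.

    Parameters
    ----------
    sd_threshold : float, default 1.0
        Number of population SDs beyond the mean defining the accelerated
        (above) and stable (below) classes.
    min_waves : int, default 2
        Minimum usable risk values for a subject to be classifiable.
    residualize : bool, default True
        Regress raw slopes on baseline age and baseline risk before
        classifying (removes mechanical age/level dependence).

    Attributes
    ----------
    mean_, sd_ : float
        Pattern-mixture population moments of the adjusted slopes.
    coef_ : ndarray
        Residualization coefficients (intercept, baseline age, baseline
        risk); zeros when ``residualize=False``.
    labels_ : DataFrame
        Per-subject table: raw_slope, adjusted_slope, pattern, class.
    """

    def __init__(self, sd_threshold: float = 1.0, min_waves: int = 2,
                 residualize: bool = True):
        self.sd_threshold = sd_threshold
        self.min_waves = min_waves
        self.residualize = residualize

    def fit(self, series_list: list[FrsSeries], y=None):
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        sids = [s.subject_id for s in series_list]
        raw = np.array([fit_subject_slope(s, self.min_waves) for s in series_list])
        base_age = np.full(len(series_list), np.nan)
        base_frs = np.full(len(series_list), np.nan)
        pattern = np.zeros(len(series_list), dtype=int)
        for i, s in enumerate(series_list):
            if len(s):
                base_frs[i] = s.risks[0]
                pattern[i] = max(s.waves)
        self._baseline_age_from(series_list, base_age)

        ok = ~np.isnan(raw)
        if not ok.any():
            raise ValueError("no classifiable subjects (all series too short)")
        adjusted = raw.copy()
        if self.residualize:
            X = np.column_stack([np.ones(ok.sum()), base_age[ok], base_frs[ok]])
            # baseline age may be unavailable when series were built without
            # ages; drop the column rather than fail
            if np.isnan(X[:, 1]).any():
                X = X[:, [0, 2]]
            coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
            adjusted[ok] = raw[ok] - X @ coef
            self.coef_ = coef
        else:
            self.coef_ = np.zeros(3)

        self.mean_, self.sd_ = pattern_mixture_moments(adjusted[ok], pattern[ok])
        cls = classify(adjusted, self.mean_, self.sd_, self.sd_threshold)
        self.labels_ = pd.DataFrame(
            {
                "subject_id": sids,
                "raw_slope": raw,
                "adjusted_slope": adjusted,
                "pattern": pattern,
                "class": cls,
            }
        )
        return self

    def _baseline_age_from(self, series_list, base_age) -> None:
        for i, s in enumerate(series_list):
            age = getattr(s, "baseline_age", None)
            if age is not None:
                base_age[i] = age

    def predict(self, series_list: list[FrsSeries]) -> np.ndarray:
        """Classify new series against the fitted moments."""
        raw = np.array([fit_subject_slope(s, self.min_waves) for s in series_list])
        if self.residualize and len(self.coef_) >= 2:
            frs0 = np.array([s.risks[0] if len(s) else np.nan for s in series_list])
            if len(self.coef_) == 2:
                raw = raw - (self.coef_[0] + self.coef_[1] * frs0)
            else:
                age0 = np.array(
                    [getattr(s, "baseline_age", np.nan) for s in series_list]
                )
                raw = raw - (
                    self.coef_[0] + self.coef_[1] * age0 + self.coef_[2] * frs0
                )
        return classify(raw, self.mean_, self.sd_, self.sd_threshold)


def label_cohort(
    cohort: pd.DataFrame,
    config: TrajectoryConfig | None = None,
    constants: dict | None = None,
    wave_spacing_years: float = 5.0,
) -> pd.DataFrame:
    """Build per-subject risk series from a long cohort table and classify.

    Returns the per-subject label table (subject_id, raw_slope,
    adjusted_slope, pattern, class) in the on-disk CSV dialect.
    """
    config = config or TrajectoryConfig()
    series = [
        build_frs_series(rows, wave_spacing_years, constants)
        for _, rows in cohort.groupby("subject_id", sort=True)
    ]
    clf = TrajectoryClassifier(
        sd_threshold=config.sd_threshold,
        min_waves=config.min_waves,
        residualize=len(config.adjust_for) > 0,
    ).fit(series)
    return clf.labels_
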