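"""Episodic-memory composite and relative decline events.

The EM composite is the exact sum of five recall-task scores (range 0-76).
Because memory declines with normal aging, raw drops are not informative;
a *relative* decline event is defined against age norms: at each wave a
subject's composite is residualized against the mean composite of
same-age peers (within ``age_norm_window`` years at that wave), and the
event is the first wave at which the residualized score falls at least
``threshold_sd`` pooled SDs below the subject's own baseline residualized
score.  Subjects never reaching that drop are censored at their last
observation.  The analysis targets the younger stratum (entry age at most
``max_entry_age``), where decline precedes any dementia diagnosis.

The resulting event table feeds the same person-period + probit-BART +
standardization machinery as the dementia analysis, as a two-state
(no-decline -> decline) model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DeclineConfig", "em_composite", "decline_events", "decline_cohort"]

EM_TASK_COLS = [f"em_task{j}" for j in range(1, 6)]
EM_RANGE = (0.0, 76.0)


@dataclass
class DeclineConfig:
    threshold_sd: float = 1.0
    age_norm_window: float = 5.0
    min_waves: int = 2
    max_entry_age: float = 65.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")


def em_composite(task_scores) -> float:
    """Exact sum of the five task scores; NaN if any task is missing."""
    t = np.asarray(task_scores, dtype=float)
    if t.shape[-1] != 5:
        raise ValueError("expected 5 task scores")
    if np.any(t < 0):
        raise ValueError("task scores must be nonnegative")
    if np.any(np.isnan(t)):
        return float("nan")
    total = float(t.sum())
    if total > EM_RANGE[1]:
        raise ValueError(f"composite {total} exceeds {EM_RANGE[1]}")
    return total


def _age_residuals(df: pd.DataFrame, window: float) -> pd.Series:
    """Composite minus the mean composite of same-age (+/- window) peers
    at the same wave."""
    out = pd.Series(np.nan, index=df.index)
    for _, sub in df.groupby("wave_index"):
        ages = sub["age"].to_numpy()
        comp = sub["em_composite"].to_numpy()
        order = np.argsort(ages)
        a_sorted, c_sorted = ages[order], comp[order]
        cnt = np.concatenate([[0], np.cumsum(~np.isnan(c_sorted))])
        csum_obs = np.concatenate(
            [[0.0], np.cumsum(np.where(np.isnan(c_sorted), 0.0, c_sorted))]
        )
        lo = np.searchsorted(a_sorted, ages - window, side="left")
        hi = np.searchsorted(a_sorted, ages + window, side="right")
        norm_mean = (csum_obs[hi] - csum_obs[lo]) / np.maximum(cnt[hi] - cnt[lo], 1)
        out.loc[sub.index] = comp - norm_mean
    return out


def decline_events(
    cohort: pd.DataFrame, config: DeclineConfig | None = None
) -> pd.DataFrame:
    """Derive per-subject relative EM decline events.

    Returns a table (subject_id, event, event_wave, censor_wave); subjects
    with fewer than ``min_waves`` observed composites or entry age above
    ``max_entry_age`` are excluded.
    """
    config = config or DeclineConfig()
    df = cohort[cohort["em_composite"].notna()].copy()
    resid = _age_residuals(df, config.age_norm_window)
    df["em_resid"] = resid
    pooled_sd = float(df["em_resid"].std(ddof=0))
    if pooled_sd == 0.0:
        pooled_sd = 1.0

    rows = []
    base_age = cohort.sort_values(["subject_id", "wave_index"]).groupby(
        "subject_id"
    )["age"].first()
    for sid, sub in df.sort_values("wave_index").groupby("subject_id"):
        if base_age.loc[sid] > config.max_entry_age:
            continue
        if len(sub) < config.min_waves:
            continue
        r = sub["em_resid"].to_numpy()
        waves = sub["wave_index"].to_numpy()
        drop = r[0] - r[1:]
        hits = np.flatnonzero(drop >= config.threshold_sd * pooled_sd)
        if hits.size:
            rows.append(
                {"subject_id": sid, "event": 1,
                 "event_wave": int(waves[1 + hits[0]]),
                 "censor_wave": int(waves[1 + hits[0]])}
            )
        else:
            rows.append(
                {"subject_id": sid, "event": 0, "event_wave": np.nan,
                 "censor_wave": int(waves[-1])}
            )
    return pd.DataFrame(rows, columns=["subject_id", "event", "event_wave", "censor_wave"])


def decline_cohort(cohort: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Recast decline events as a two-state long table.

    Produces a cohort-dialect table whose ``state`` is ``healthy`` before
    the decline event and ``AD`` from the event wave on (the generic
    "ill" state of the single-transition model), so the person-period
    expansion and hazard machinery apply unchanged.
    """
    ev = events.set_index("subject_id")
    sub = cohort[cohort["subject_id"].isin(ev.index)].copy()
    ew = sub["subject_id"].map(ev["event_wave"])
    cw = sub["subject_id"].map(ev["censor_wave"])
    w = sub["wave_index"]
    sub["state"] = np.where(
        w > cw, "dropped", np.where(ew.notna() & (w >= ew), "AD", "healthy")
    )
    return sub.reset_index(drop=True)
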