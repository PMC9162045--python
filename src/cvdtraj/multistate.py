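"""Discrete-time multistate survival modelling via transition-specific BART.

The illness-death structure (healthy -> dementia -> death, healthy ->
death) is decoupled into one binary discrete-time hazard model per
permitted transition: the cohort is expanded into person-period format
(one row per subject per at-risk interval, binary event indicator), a
probit-BART model is fitted per transition with the interval index as an
ordinary feature (hazards are therefore freely time-varying -- no
proportionality assumption), and state-occupation / cumulative-incidence
curves are composed by forward recursion over the per-draw transition
probabilities.

A nonparametric counterpart, :func:`aalen_johansen`, computes the
discrete-time cause-specific cumulative-incidence estimate from crude
per-interval event fractions; on covariate-free data the BART-based
curves must agree with it, which is the module's principal oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bart import BartPosterior, BartProbitClassifier

__all__ = [
    "TransitionSpec",
    "ILLNESS_DEATH",
    "AD_VAD_SPLIT",
    "SINGLE_EVENT",
    "PersonPeriodTable",
    "expand_person_period",
    "fit_transitions",
    "occupation_curves",
    "aalen_johansen",
    "GROUP_CODES",
]

log = logging.getLogger(__name__)

#: integer encoding of the trajectory classes used as a model feature
GROUP_CODES = {"stable": 0, "average": 1, "accelerated": 2}

#: baseline confounders entering every transition model
BASE_FEATURES = ["baseline_age", "sex_code", "education_years", "apoe4_code"]


@dataclass(frozen=True)
class TransitionSpec:
    name: str
    origin: str  # "healthy" | "dementia" | "origin" (single-event model)
    destination: str  # "dementia" | "AD" | "VaD" | "death" | "event"

    def origin_matches(self, state: str) -> bool:
        if self.origin == "dementia":
            return state in ("AD", "VaD")
        return state == self.origin

    def destination_matches(self, state: str) -> bool:
        if self.destination == "dementia":
            return state in ("AD", "VaD")
        if self.destination == "death":
            return state == "dead"
        return state == self.destination


ILLNESS_DEATH = (
    TransitionSpec("healthy->dementia", "healthy", "dementia"),
    TransitionSpec("healthy->death", "healthy", "death"),
    TransitionSpec("dementia->death", "dementia", "death"),
)

AD_VAD_SPLIT = (
    TransitionSpec("healthy->AD", "healthy", "AD"),
    TransitionSpec("healthy->VaD", "healthy", "VaD"),
    TransitionSpec("healthy->death", "healthy", "death"),
    TransitionSpec("dementia->death", "dementia", "death"),
)

#: two-state model for episodic-memory decline events; the generic "ill"
#: state of the event table is encoded with the dementia state labels
SINGLE_EVENT = (TransitionSpec("nodecline->decline", "healthy", "dementia"),)


@dataclass
class PersonPeriodTable:
    """Person-period expansion of one transition.

    ``frame`` holds one row per subject per at-risk interval with the
    binary ``event`` indicator; ``feature_cols`` are the model features
    (interval index, baseline confounders, trajectory-group code).
    """

    spec: TransitionSpec
    frame: pd.DataFrame
    feature_cols: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


class StateSequenceError(ValueError):
    pass


_STATE_ORDER = {"healthy": 0, "AD": 1, "VaD": 1, "dead": 2, "dropped": 3}


def _validate_sequence(sid, states: list[str]) -> None:
    """healthy -> {AD|VaD} -> dead, no resurrection, no type switching,
    'dropped' only as a terminal run."""
    seen_dem = None
    prev = -1
    for s in states:
        o = _STATE_ORDER[s]
        if o == 3:
            prev = 3
            continue
        if prev == 3:
            raise StateSequenceError(f"subject {sid}: observed wave after dropout")
        if o < prev:
            raise StateSequenceError(f"subject {sid}: state sequence not monotone")
        if s in ("AD", "VaD"):
            if seen_dem is not None and s != seen_dem:
                raise StateSequenceError(f"subject {sid}: dementia type switches")
            seen_dem = s
        prev = o


def expand_person_period(
    cohort: pd.DataFrame,
    specs=ILLNESS_DEATH,
    groups: pd.Series | None = None,
    group_codes: dict | None = None,
    min_entry_age: float | None = None,
    max_entry_age: float | None = None,
) -> dict[str, PersonPeriodTable]:
    """Expand a long cohort table into per-transition person-period tables.

    Interval ``k`` covers the step from wave ``k`` to wave ``k+1``; a
    subject contributes a row to a transition at interval ``k`` while
    occupying its origin state at wave ``k`` with wave ``k+1`` observed
    (dropout censors).  ``groups`` maps subject_id -> trajectory class (or
    any exposure grouping); subjects without a group (e.g. unclassified)
    are excluded.  ``min_entry_age``/``max_entry_age`` restrict by age at
    the subject's first wave (the dementia analysis uses >= 70, the
    memory-decline analysis <= 65).
    """
    group_codes = group_codes or GROUP_CODES
    base = (
        cohort.sort_values(["subject_id", "wave_index"])
        .groupby("subject_id")
        .first()
    )
    keep = pd.Series(True, index=base.index)
    if min_entry_age is not None:
        keep &= base["age"] >= min_entry_age
    if max_entry_age is not None:
        keep &= base["age"] <= max_entry_age
    if groups is not None:
        g = pd.Series(groups)
        code = g.map(group_codes)
        keep &= base.index.isin(code.dropna().index)

    rows_per = {sp.name: [] for sp in specs}
    for sid, sub in cohort.sort_values(["subject_id", "wave_index"]).groupby(
        "subject_id"
    ):
        if not keep.get(sid, False):
            continue
        states = list(sub["state"])
        waves = list(sub["wave_index"])
        _validate_sequence(sid, states)
        b = sub.iloc[0]
        feat = {
            "baseline_age": float(b["age"]),
            "sex_code": 1.0 if b["sex"] == "male" else 0.0,
            "education_years": float(b["education_years"]),
            "apoe4_code": 1.0 if b["apoe4"] == "carrier" else 0.0,
        }
        gcode = float(group_codes[groups.loc[sid]]) if groups is not None else 0.0
        for i in range(len(waves) - 1):
            s_now, s_next = states[i], states[i + 1]
            if s_next == "dropped" or s_now == "dropped":
                break
            for sp in specs:
                if sp.origin_matches(s_now):
                    rows_per[sp.name].append(
                        {
                            "subject_id": sid,
                            "interval": int(waves[i]),
                            "event": 1 if sp.destination_matches(s_next) else 0,
                            "group_code": gcode,
                            **feat,
                        }
                    )

    feature_cols = ["interval"] + BASE_FEATURES + ["group_code"]
    out = {}
    for sp in specs:
        frame = pd.DataFrame(
            rows_per[sp.name],
            columns=["subject_id", "interval", "event", "group_code"]
            + BASE_FEATURES,
        )
        out[sp.name] = PersonPeriodTable(sp, frame, feature_cols)
    return out


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject baseline confounders in model-feature encoding."""
    base = (
        cohort.sort_values(["subject_id", "wave_index"])
        .groupby("subject_id")
        .first()
        .reset_index()
    )
    return pd.DataFrame(
        {
            "subject_id": base["subject_id"],
            "baseline_age": base["age"].astype(float),
            "sex_code": (base["sex"] == "male").astype(float),
            "education_years": base["education_years"].astype(float),
            "apoe4_code": (base["apoe4"] == "carrier").astype(float),
        }
    )


def fit_transitions(
    tables: dict[str, PersonPeriodTable],
    n_trees: int = 50,
    n_burn: int = 250,
    n_draws: int = 1000,
    random_state: int = 0,
    **bart_kw,
) -> dict[str, BartPosterior]:
    """One probit-BART discrete-hazard fit per transition."""
    posteriors = {}
    for i, (name, tab) in enumerate(tables.items()):
        if tab.n_events == 0:
            raise ValueError(
                f"transition {name} has zero events; increase the synthetic "
                "hazard or pool transitions"
            )
        X = tab.frame[tab.feature_cols]
        y = tab.frame["event"].to_numpy()
        clf = BartProbitClassifier(
            n_trees=n_trees,
            n_burn=n_burn,
            n_draws=n_draws,
            random_state=random_state + 7919 * i,
            **bart_kw,
        ).fit(X, y)
        posteriors[name] = clf.posterior_
        log.info(
            "fitted %s: %d rows, %d events", name, len(tab.frame), tab.n_events
        )
    return posteriors


def _hazard_cube(posterior: BartPosterior, profiles: pd.DataFrame, intervals):
    """Predicted hazards, shape (n_draws, n_rows, n_intervals)."""
    n = len(profiles)
    X = profiles.loc[profiles.index.repeat(len(intervals))].copy()
    X["interval"] = np.tile(np.asarray(intervals, dtype=float), n)
    cols = posterior.feature_names
    draws = posterior.predict_draws(X[cols])
    return draws.reshape(draws.shape[0], n, len(intervals))


def occupation_curves(
    posteriors: dict[str, BartPosterior],
    profiles: pd.DataFrame,
    n_waves: int = 6,
    model: str = "illness-death",
    average_rows: bool = False,
    draw_indices=None,
):
    """Forward-compose per-draw state-occupation and cumulative incidence.

    ``profiles`` holds one row per covariate profile with the transition
    models' baseline features and ``group_code``.  Mass starts at 1 in the
    healthy state; at each interval it moves by the draw's transition
    probabilities.  If a draw's summed exit probabilities from one origin
    exceed 1 (rare), they are renormalized to 1 and the case is logged.
    Cumulative incidence of a destination is its cumulated inflow.

    Returns a dict state/incidence-name -> array of shape
    ``(n_draws, n_rows, n_waves)`` (rows axis dropped if ``average_rows``).
    """
    intervals = np.arange(1, n_waves, dtype=float)
    if model == "illness-death":
        names = ["healthy->dementia", "healthy->death", "dementia->death"]
        dem_states = ["dementia"]
    elif model == "ad-vad":
        names = ["healthy->AD", "healthy->VaD", "healthy->death", "dementia->death"]
        dem_states = ["AD", "VaD"]
    elif model == "single":
        names = [next(iter(posteriors))]
        dem_states = []
    else:
        raise ValueError(f"unknown model {model!r}")
    missing = [n_ for n_ in names if n_ not in posteriors]
    if missing:
        raise ValueError(f"missing fitted transitions: {missing}")

    cubes = {}
    for n_ in names:
        cube = _hazard_cube(posteriors[n_], profiles, intervals)
        if draw_indices is not None:
            cube = cube[draw_indices]
        cubes[n_] = cube
    D, R, _ = cubes[names[0]].shape

    if model == "single":
        h = cubes[names[0]]
        surv = np.cumprod(1.0 - h, axis=2)
        inc = 1.0 - surv
        out = {
            "healthy": np.concatenate([np.ones((D, R, 1)), surv], axis=2),
            "cuminc_event": np.concatenate([np.zeros((D, R, 1)), inc], axis=2),
        }
        return _maybe_avg(out, average_rows)

    p_h = np.ones((D, R))
    p_dem = {s: np.zeros((D, R)) for s in dem_states}
    p_dead = np.zeros((D, R))
    cuminc = {s: np.zeros((D, R)) for s in dem_states}
    cuminc_death = np.zeros((D, R))
    # deaths straight from healthy: the competing-risk complement of the
    # dementia incidences (dementia deaths are counted in cuminc_death only)
    cuminc_death_healthy = np.zeros((D, R))

    occ = {
        "healthy": [p_h.copy()],
        "dead": [p_dead.copy()],
        **{s: [p_dem[s].copy()] for s in dem_states},
    }
    cum = {f"cuminc_{s}": [cuminc[s].copy()] for s in dem_states}
    cum["cuminc_death"] = [cuminc_death.copy()]
    cum["cuminc_death_healthy"] = [cuminc_death_healthy.copy()]

    dem_names = names[:-2] if model == "ad-vad" else names[:1]
    for t in range(len(intervals)):
        h_dem = {n_: cubes[n_][:, :, t] for n_ in dem_names}
        h_hx = cubes["healthy->death"][:, :, t]
        total_exit = sum(h_dem.values()) + h_hx
        over = total_exit > 1.0
        if over.any():
            log.warning(
                "renormalizing %d draw-row exit probabilities > 1 at interval %d",
                int(over.sum()), t + 1,
            )
            scale = np.where(over, 1.0 / total_exit, 1.0)
            h_hx = h_hx * scale
            h_dem = {k: v * scale for k, v in h_dem.items()}
        h_dd = cubes["dementia->death"][:, :, t]

        inflow_dem = {}
        for n_, s in zip(dem_names, dem_states):
            inflow_dem[s] = p_h * h_dem[n_]
        dem_deaths = {s: p_dem[s] * h_dd for s in dem_states}
        death_from_healthy = p_h * h_hx
        death_in = death_from_healthy + sum(dem_deaths.values())

        p_h = p_h * (1.0 - sum(h_dem.values()) - h_hx)
        for s in dem_states:
            p_dem[s] = p_dem[s] - dem_deaths[s] + inflow_dem[s]
            cuminc[s] = cuminc[s] + inflow_dem[s]
        p_dead = p_dead + death_in
        cuminc_death = cuminc_death + death_in
        cuminc_death_healthy = cuminc_death_healthy + death_from_healthy

        occ["healthy"].append(p_h.copy())
        occ["dead"].append(p_dead.copy())
        for s in dem_states:
            occ[s].append(p_dem[s].copy())
            cum[f"cuminc_{s}"].append(cuminc[s].copy())
        cum["cuminc_death"].append(cuminc_death.copy())
        cum["cuminc_death_healthy"].append(cuminc_death_healthy.copy())

    out = {k: np.stack(v, axis=2) for k, v in {**occ, **cum}.items()}
    return _maybe_avg(out, average_rows)


def _maybe_avg(out, average_rows):
    if average_rows:
        return {k: v.mean(axis=1) for k, v in out.items()}
    return out


def aalen_johansen(
    tables: dict[str, PersonPeriodTable], n_waves: int = 6, model: str = "illness-death"
) -> dict[str, np.ndarray]:
    """Discrete-time nonparametric state occupation / cumulative incidence.

    Crude per-interval cause-specific hazards (events over at-risk count)
    plugged into the same forward recursion as the model-based curves.
    """
    intervals = np.arange(1, n_waves)

    def crude(name):
        fr = tables[name].frame
        h = np.zeros(len(intervals))
        for i, k in enumerate(intervals):
            rows = fr[fr["interval"] == k]
            h[i] = rows["event"].mean() if len(rows) else 0.0
        return h

    if model == "single":
        name = next(iter(tables))
        h = crude(name)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - h)])
        return {"healthy": surv, "cuminc_event": 1.0 - surv}

    if model == "illness-death":
        dem_names, dem_states = ["healthy->dementia"], ["dementia"]
    else:
        dem_names, dem_states = ["healthy->AD", "healthy->VaD"], ["AD", "VaD"]
    h_dem = {s: crude(n_) for n_, s in zip(dem_names, dem_states)}
    h_hx = crude("healthy->death")
    h_dd = crude("dementia->death")

    p_h, p_dead = 1.0, 0.0
    p_dem = {s: 0.0 for s in dem_states}
    ci = {s: [0.0] for s in dem_states}
    ci_death = [0.0]
    occ_h, occ_dead = [1.0], [0.0]
    occ_dem = {s: [0.0] for s in dem_states}
    for t in range(len(intervals)):
        inflow = {s: p_h * h_dem[s][t] for s in dem_states}
        dem_death = {s: p_dem[s] * h_dd[t] for s in dem_states}
        death_in = p_h * h_hx[t] + sum(dem_death.values())
        p_h = p_h * (1.0 - sum(h_dem[s][t] for s in dem_states) - h_hx[t])
        for s in dem_states:
            p_dem[s] = p_dem[s] - dem_death[s] + inflow[s]
            ci[s].append(ci[s][-1] + inflow[s])
            occ_dem[s].append(p_dem[s])
        p_dead = p_dead + death_in
        ci_death.append(ci_death[-1] + death_in)
        occ_h.append(p_h)
        occ_dead.append(p_dead)
    out = {"healthy": np.array(occ_h), "dead": np.array(occ_dead),
           "cuminc_death": np.array(ci_death)}
    for s in dem_states:
        out[s] = np.array(occ_dem[s])
        out[f"cuminc_{s}"] = np.array(ci[s])
    return out
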