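"""BART-based multiple imputation of missing risk-factor covariates.

Item-level gaps in the Framingham inputs (SBP, BMI, smoking, diabetes,
blood-pressure medication) are assumed missing at random given the always
observed demographics.  Imputation is a chained-equations scheme with a
BART model per variable: missing entries are initialized by draws from the
observed marginal, then the scheme cycles over the incomplete variables,
fitting a BART model (continuous, or probit for binaries) of each on all
other risk factors plus age, sex, wave, and the subject's own observed
mean of the target variable at other waves (leave-one-out, so the cell
being modelled never predicts itself) -- in a longitudinal cohort the
subject's other waves are by far the strongest predictor of a missing
cell -- and replacing the missing entries with posterior-predictive
draws.  After ``n_cycles`` cycles one completed table is emitted; the
whole scheme runs ``m`` times with independent sub-seeds, giving ``m``
completed cohorts whose downstream analyses are pooled by simple mixing
of posterior draws.

Observed cells are never altered, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bart import BartProbitClassifier, BartRegressor
from .cohort import FRS_COVARIATES

__all__ = ["ImputationConfig", "BartImputer", "impute_covariates"]

_BINARY = {"bp_medication", "smoker", "diabetes"}
_ALWAYS_OBSERVED = ["age", "wave_index"]


@dataclass
class ImputationConfig:
    variables_to_impute: tuple[str, ...] = tuple(FRS_COVARIATES)
    n_cycles: int = 5
    m: int = 5
    n_trees: int = 20
    n_burn: int = 50
    n_draws: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_cycles < 1:
            raise ValueError("m and n_cycles must be >= 1")


def _loo_subject_mean(subject_ids: pd.Series, values: pd.Series) -> np.ndarray:
    """Leave-one-out mean of each subject's *observed* values of a variable.

    For a row whose own cell is observed, its value is excluded; rows of
    subjects with no other observed wave fall back to the overall mean.
    Computed once from the original observed cells, so it is identical in
    every chained-equations cycle.
    """
    v = values.astype(float)
    obs = v.notna()
    grp = v.where(obs).groupby(subject_ids)
    total = grp.transform("sum")
    count = grp.transform("count")
    own = v.where(obs, 0.0)
    n_other = count - obs.astype(int)
    loo = (total - own) / n_other.where(n_other > 0)
    return loo.fillna(v[obs].mean()).to_numpy()


class BartImputer(BaseEstimator):
    """Chained-equations imputer with BART conditional models.

    ``transform`` returns a list of ``m`` completed copies of the cohort;
    with no missing entries the copies equal the input.
    """

    def __init__(self, variables=tuple(FRS_COVARIATES), n_cycles=5, m=5,
                 n_trees=20, n_burn=50, n_draws=10, random_state=0):
        self.variables = variables
        self.n_cycles = n_cycles
        self.m = m
        self.n_trees = n_trees
        self.n_burn = n_burn
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, cohort: pd.DataFrame, y=None):
        for v in self.variables:
            col = cohort[v]
            if col.notna().sum() == 0:
                raise ValueError(
                    f"variable {v!r} has zero observed values; cannot impute"
                )
        self.n_features_in_ = cohort.shape[1]
        return self

    def transform(self, cohort: pd.DataFrame) -> list[pd.DataFrame]:
        self.fit(cohort)
        rows = cohort["state"].isin(["healthy", "AD", "VaD"])  # measured rows
        out = []
        for im in range(self.m):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.random_state, im])
            )
            out.append(self._one_imputation(cohort, rows, rng, im))
        return out

    fit_transform = transform

    def _one_imputation(self, cohort, rows, rng, im):
        df = cohort.copy()
        sub = df.loc[rows]
        miss = {v: sub[v].isna() for v in self.variables}
        todo = [v for v in self.variables if miss[v].any()]
        if not todo:
            return df

        # initialize from observed marginals
        work = sub.copy()
        for v in todo:
            obs = work.loc[~miss[v], v].to_numpy()
            work.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()))

        sex_code = (work["sex"] == "male").astype(float)
        subj_mean = {
            v: _loo_subject_mean(sub["subject_id"], sub[v]) for v in todo
        }
        for cyc in range(self.n_cycles):
            for vi, v in enumerate(todo):
                others = [c for c in self.variables if c != v]
                X = work[others + _ALWAYS_OBSERVED].astype(float).copy()
                X["sex_code"] = sex_code
                X["subj_mean"] = subj_mean[v]
                obs_mask = ~miss[v]
                seed = int(
                    np.random.default_rng(
                        np.random.SeedSequence(
                            [self.random_state, im, cyc, vi]
                        )
                    ).integers(2**31 - 1)
                )
                y_obs = work.loc[obs_mask, v].astype(float).to_numpy()
                X_obs, X_mis = X[obs_mask], X[miss[v]]
                if v in _BINARY:
                    if np.unique(y_obs).size < 2:
                        # degenerate: keep the marginal draws
                        continue
                    model = BartProbitClassifier(
                        n_trees=self.n_trees, n_burn=self.n_burn,
                        n_draws=self.n_draws, random_state=seed,
                    ).fit(X_obs, y_obs.astype(int))
                    p = model.predict_draws(X_mis)[-1]
                    work.loc[miss[v], v] = (
                        rng.random(p.size) < p
                    ).astype(float)
                else:
                    model = BartRegressor(
                        n_trees=self.n_trees, n_burn=self.n_burn,
                        n_draws=self.n_draws, random_state=seed,
                    ).fit(X_obs, y_obs)
                    f = model.predict_draws(X_mis)[-1]
                    sig = model.posterior_.sigma[-1]
                    work.loc[miss[v], v] = f + sig * rng.standard_normal(f.size)
        cols = list(self.variables)
        df.loc[rows, cols] = work[cols]
        return df


def impute_covariates(
    cohort: pd.DataFrame, config: ImputationConfig | None = None
) -> list[pd.DataFrame]:
    """Functional wrapper over :class:`BartImputer`."""
    config = config or ImputationConfig()
    imp = BartImputer(
        variables=config.variables_to_impute,
        n_cycles=config.n_cycles,
        m=config.m,
        n_trees=config.n_trees,
        n_burn=config.n_burn,
        n_draws=config.n_draws,
        random_state=config.seed,
    )
    return imp.fit_transform(cohort)
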