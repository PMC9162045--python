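"""Bayesian additive regression trees (BART).

A self-contained sum-of-trees sampler: the response is modelled as the sum
of many shallow regression trees plus Gaussian noise, with a regularization
prior that keeps individual trees weak — node at depth ``d`` splits with
probability ``alpha * (1 + d) ** -beta``, split rules are uniform over
features and their observed-quantile cutpoints, and leaf values are iid
``N(0, sigma_mu^2)`` with ``sigma_mu`` shrinking as the number of trees
grows.  Sampling is backfitting MCMC: each tree in turn receives a
grow/prune/change structure proposal accepted by Metropolis-Hastings under
the leaf-marginalized likelihood, after which leaf values and (for
continuous outcomes) the error variance are redrawn from their conjugate
posteriors.  Binary outcomes use probit latent-normal augmentation with
unit error variance and an offset at the sample base rate.

Two scikit-learn style estimators wrap the sampler: :class:`BartRegressor`
and :class:`BartProbitClassifier`.  Both keep every retained posterior draw
(``predict_draws``) because downstream standardization needs per-draw
curves, not premature averages.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

__all__ = ["BartRegressor", "BartProbitClassifier", "BartPosterior"]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# tree machinery
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("feature", "cut", "left", "right", "value", "rows", "depth")

    def __init__(self, rows, depth):
        self.feature = -1  # -1 marks a leaf
        self.cut = 0.0
        self.left = None
        self.right = None
        self.value = 0.0
        self.rows = rows
        self.depth = depth

    @property
    def is_leaf(self):
        return self.feature < 0


def _leaves(node, out):
    if node.is_leaf:
        out.append(node)
    else:
        _leaves(node.left, out)
        _leaves(node.right, out)
    return out


def _singly_internal(node, out):
    """Internal nodes whose both children are leaves (prunable/changeable)."""
    if node.is_leaf:
        return out
    if node.left.is_leaf and node.right.is_leaf:
        out.append(node)
    _singly_internal(node.left, out)
    _singly_internal(node.right, out)
    return out


def _flatten(node):
    """Snapshot a tree into flat arrays (feature, cut, left, right, value)."""
    feat, cut, left, right, val = [], [], [], [], []

    def rec(nd):
        idx = len(feat)
        feat.append(nd.feature)
        cut.append(nd.cut)
        left.append(-1)
        right.append(-1)
        val.append(nd.value)
        if not nd.is_leaf:
            left[idx] = rec(nd.left)
            right[idx] = rec(nd.right)
        return idx

    rec(node)
    return (
        np.array(feat, dtype=np.int32),
        np.array(cut, dtype=np.float64),
        np.array(left, dtype=np.int32),
        np.array(right, dtype=np.int32),
        np.array(val, dtype=np.float64),
    )


def _eval_flat(tree, X):
    """Vectorized evaluation of one flattened tree on X (n, p)."""
    feat, cut, left, right, val = tree
    idx = np.zeros(X.shape[0], dtype=np.int32)
    active = feat[idx] >= 0
    while active.any():
        ai = np.flatnonzero(active)
        node = idx[ai]
        go_left = X[ai, feat[node]] <= cut[node]
        idx[ai] = np.where(go_left, left[node], right[node])
        active[ai] = feat[idx[ai]] >= 0
    return val[idx]


class _Sampler:
    """Backfitting MCMC over a forest, on the internal (centered) scale."""

    def __init__(self, X, y, n_trees, alpha, beta, sigma_mu, rng,
                 p_grow=0.25, p_prune=0.25, max_cutpoints=100):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        self.n_trees = n_trees
        self.alpha = alpha
        self.beta = beta
        self.tau2 = sigma_mu**2
        self.rng = rng
        self.p_grow = p_grow
        self.p_prune = p_prune
        self.cutpoints = []
        for j in range(self.p):
            uniq = np.unique(X[:, j])
            cand = uniq[:-1]  # split "x <= c": every boundary but the max
            if cand.size > max_cutpoints:
                qs = np.linspace(0, 1, max_cutpoints + 2)[1:-1]
                cand = np.unique(np.quantile(cand, qs))
            self.cutpoints.append(cand)
        all_rows = np.arange(self.n)
        self.trees = [_Node(all_rows, 0) for _ in range(n_trees)]
        self.tree_fit = np.zeros((n_trees, self.n))
        self.total_fit = np.zeros(self.n)
        self.sigma2 = 1.0

    # -- structural helpers --------------------------------------------

    def _valid_cuts(self, node, j):
        xj = self.X[node.rows, j]
        lo, hi = xj.min(), xj.max()
        if lo == hi:
            return None
        cand = self.cutpoints[j]
        cuts = cand[(cand >= lo) & (cand < hi)]
        return cuts if cuts.size else None

    def _growable(self, node):
        return any(self._valid_cuts(node, j) is not None for j in range(self.p))

    def _split_prob(self, depth):
        return self.alpha * (1.0 + depth) ** (-self.beta)

    def _log_depth_prior(self, depth):
        ps = self._split_prob(depth)
        pc = self._split_prob(depth + 1)
        return np.log(ps) + 2.0 * np.log1p(-pc) - np.log1p(-ps)

    def _move_probs(self, tree):
        # a stump can only grow; otherwise the configured mix
        if tree.is_leaf:
            return 1.0, 0.0
        return self.p_grow, self.p_prune

    def _ml_core(self, n, s):
        # marginal-likelihood terms that do not cancel between parent and
        # children (same rows, same sigma): -0.5 log(1 + n tau2/sig2)
        #                                   + tau2 s^2 / (2 sig2 (sig2 + n tau2))
        sig2 = self.sigma2
        return (
            -0.5 * np.log1p(n * self.tau2 / sig2)
            + self.tau2 * s * s / (2.0 * sig2 * (sig2 + n * self.tau2))
        )

    # -- one tree update -----------------------------------------------

    def update_tree(self, t, resid):
        tree = self.trees[t]
        pg, pp = self._move_probs(tree)
        u = self.rng.random()
        if u < pg:
            self._grow(tree, resid)
        elif u < pg + pp:
            self._prune(tree, resid)
        else:
            self._change(tree, resid)
        # redraw every leaf value from its conjugate normal posterior
        leaves = _leaves(tree, [])
        fit = self.tree_fit[t]
        newfit = np.empty(self.n)
        for leaf in leaves:
            nl = leaf.rows.size
            s = resid[leaf.rows].sum()
            var = 1.0 / (1.0 / self.tau2 + nl / self.sigma2)
            mean = var * s / self.sigma2
            leaf.value = mean + np.sqrt(var) * self.rng.standard_normal()
            newfit[leaf.rows] = leaf.value
        self.total_fit += newfit - fit
        self.tree_fit[t] = newfit

    def _grow(self, tree, resid):
        leaves = _leaves(tree, [])
        growable = [nd for nd in leaves if self._growable(nd)]
        if not growable:
            return
        node = growable[self.rng.integers(len(growable))]
        feats = [j for j in range(self.p) if self._valid_cuts(node, j) is not None]
        j = feats[self.rng.integers(len(feats))]
        cuts = self._valid_cuts(node, j)
        c = cuts[self.rng.integers(cuts.size)]

        mask = self.X[node.rows, j] <= c
        rows_l, rows_r = node.rows[mask], node.rows[~mask]
        r = resid[node.rows]
        s_p = r.sum()
        s_l = r[mask].sum()
        log_lik = (
            self._ml_core(rows_l.size, s_l)
            + self._ml_core(rows_r.size, s_p - s_l)
            - self._ml_core(node.rows.size, s_p)
        )

        # counts for the transition ratio in the proposed tree
        node.feature, node.cut = j, c
        node.left = _Node(rows_l, node.depth + 1)
        node.right = _Node(rows_r, node.depth + 1)
        n_prunable_new = len(_singly_internal(tree, []))
        pg_cur, _ = (1.0, 0.0) if len(leaves) == 1 else (self.p_grow, self.p_prune)
        pp_new = self.p_prune

        log_accept = (
            np.log(pp_new / pg_cur)
            + np.log(len(growable))
            - np.log(n_prunable_new)
            + self._log_depth_prior(node.depth)
            + log_lik
        )
        if np.log(self.rng.random() + _EPS) >= log_accept:
            node.feature, node.left, node.right = -1, None, None  # reject

    def _prune(self, tree, resid):
        prunable = _singly_internal(tree, [])
        if not prunable:
            return
        node = prunable[self.rng.integers(len(prunable))]
        r_l = resid[node.left.rows]
        r_r = resid[node.right.rows]
        s_l, s_r = r_l.sum(), r_r.sum()
        log_lik = (
            self._ml_core(node.rows.size, s_l + s_r)
            - self._ml_core(node.left.rows.size, s_l)
            - self._ml_core(node.right.rows.size, s_r)
        )
        feature, cut, left, right = node.feature, node.cut, node.left, node.right
        node.feature, node.left, node.right = -1, None, None
        leaves_new = _leaves(tree, [])
        growable_new = [nd for nd in leaves_new if self._growable(nd)]
        pg_new, _ = (1.0, 0.0) if len(leaves_new) == 1 else (self.p_grow, self.p_prune)
        log_accept = (
            np.log(pg_new / self.p_prune)
            + np.log(len(prunable))
            - np.log(max(len(growable_new), 1))
            - self._log_depth_prior(node.depth)
            + log_lik
        )
        if np.log(self.rng.random() + _EPS) >= log_accept:
            node.feature, node.cut = feature, cut  # reject: restore
            node.left, node.right = left, right

    def _change(self, tree, resid):
        nodes = _singly_internal(tree, [])
        if not nodes:
            return
        node = nodes[self.rng.integers(len(nodes))]
        feats = [j for j in range(self.p) if self._valid_cuts(node, j) is not None]
        if not feats:
            return
        j = feats[self.rng.integers(len(feats))]
        cuts = self._valid_cuts(node, j)
        c = cuts[self.rng.integers(cuts.size)]

        r = resid[node.rows]
        mask_new = self.X[node.rows, j] <= c
        s_p = r.sum()
        s_l_new = r[mask_new].sum()
        n_l_new = int(mask_new.sum())
        s_l_old = resid[node.left.rows].sum()
        log_lik = (
            self._ml_core(n_l_new, s_l_new)
            + self._ml_core(node.rows.size - n_l_new, s_p - s_l_new)
            - self._ml_core(node.left.rows.size, s_l_old)
            - self._ml_core(node.right.rows.size, s_p - s_l_old)
        )
        if np.log(self.rng.random() + _EPS) < log_lik:
            node.feature, node.cut = j, c
            node.left.rows = node.rows[mask_new]
            node.right.rows = node.rows[~mask_new]

    def snapshot(self):
        return [_flatten(tree) for tree in self.trees]


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

class BartPosterior:
    """Stored forest draws plus the metadata needed to predict.

    ``forests`` is a list (one per retained draw) of flattened trees;
    ``sigma`` holds the per-draw error SD on the original outcome scale
    (continuous outcomes only).
    """

    def __init__(self, forests, kind, feature_names, offset=0.0,
                 y_loc=0.0, y_scale=1.0, sigma=None):
        self.forests = forests
        self.kind = kind
        self.feature_names = list(feature_names)
        self.offset = float(offset)
        self.y_loc = float(y_loc)
        self.y_scale = float(y_scale)
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)

    @property
    def n_draws(self):
        return len(self.forests)

    def _as_matrix(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"prediction features missing: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features "
                    f"{self.feature_names}, got shape {X.shape}"
                )
        return X

    def predict_draws(self, X):
        """Draw-by-row prediction matrix (n_draws, n_rows).

        Continuous: outcome-scale means.  Probit: event probabilities,
        strictly inside (0, 1).
        """
        X = self._as_matrix(X)
        out = np.empty((self.n_draws, X.shape[0]))
        for d, forest in enumerate(self.forests):
            f = np.zeros(X.shape[0])
            for tree in forest:
                f += _eval_flat(tree, X)
            out[d] = f
        out += self.offset
        if self.kind == "probit":
            return np.clip(special.ndtr(out), 1e-9, 1.0 - 1e-9)
        return out * self.y_scale + self.y_loc

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "offset": self.offset,
            "y_loc": self.y_loc,
            "y_scale": self.y_scale,
            "sigma": None if self.sigma is None else self.sigma.tolist(),
            "forests": [
                [[arr.tolist() for arr in tree] for tree in forest]
                for forest in self.forests
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "BartPosterior":
        d = json.loads(text)
        forests = [
            [
                (
                    np.array(t[0], dtype=np.int32),
                    np.array(t[1], dtype=np.float64),
                    np.array(t[2], dtype=np.int32),
                    np.array(t[3], dtype=np.int32),
                    np.array(t[4], dtype=np.float64),
                )
                for t in forest
            ]
            for forest in d["forests"]
        ]
        return cls(
            forests,
            d["kind"],
            d["feature_names"],
            d["offset"],
            d["y_loc"],
            d["y_scale"],
            d["sigma"],
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _prep_X(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


class BartRegressor(BaseEstimator, RegressorMixin):
    """BART for continuous outcomes.

    Parameters follow the canonical formulation: ``n_trees`` weak trees,
    split-probability prior ``alpha * (1+depth) ** -beta``, leaf-scale
    parameter ``k`` (the implied half-range of the centered outcome covers
    ``k`` prior SDs of the sum of trees), and an inverse-chi-squared error
    variance prior calibrated so the sample SD sits at the ``q`` prior
    quantile with ``nu`` degrees of freedom.
    """

    def __init__(self, n_trees=50, n_burn=250, n_draws=1000, alpha=0.95,
                 beta=2.0, k=2.0, nu=3.0, q=0.90, p_grow=0.25, p_prune=0.25,
                 max_cutpoints=100, random_state=0):
        self.n_trees = n_trees
        self.n_burn = n_burn
        self.n_draws = n_draws
        self.alpha = alpha
        self.beta = beta
        self.k = k
        self.nu = nu
        self.q = q
        self.p_grow = p_grow
        self.p_prune = p_prune
        self.max_cutpoints = max_cutpoints
        self.random_state = random_state

    def fit(self, X, y):
        X, names = _prep_X(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 observations")
        if not (0.0 < self.alpha < 1.0) or self.beta < 0:
            raise ValueError("alpha must be in (0,1) and beta >= 0")
        rng = np.random.default_rng(self.random_state)

        ymin, ymax = y.min(), y.max()
        y_scale = max(ymax - ymin, _EPS)
        yc = (y - ymin) / y_scale - 0.5
        sigma_mu = 0.5 / (self.k * np.sqrt(self.n_trees))
        smp = _Sampler(X, yc, self.n_trees, self.alpha, self.beta, sigma_mu,
                       rng, self.p_grow, self.p_prune, self.max_cutpoints)
        sd_hat = max(yc.std(), 1e-6)
        lam = sd_hat**2 * stats.chi2.ppf(1.0 - self.q, self.nu) / self.nu
        smp.sigma2 = sd_hat**2

        forests, sig_draws = [], []
        n = y.size
        for it in range(self.n_burn + self.n_draws):
            for t in range(self.n_trees):
                resid = yc - smp.total_fit + smp.tree_fit[t]
                smp.update_tree(t, resid)
            e = yc - smp.total_fit
            smp.sigma2 = (self.nu * lam + e @ e) / rng.chisquare(self.nu + n)
            if it >= self.n_burn:
                forests.append(smp.snapshot())
                sig_draws.append(np.sqrt(smp.sigma2))
        self.posterior_ = BartPosterior(
            forests, "continuous", names,
            offset=0.0, y_loc=ymin + 0.5 * y_scale, y_scale=y_scale,
            sigma=np.array(sig_draws) * y_scale,
        )
        self.sigma_trace_ = self.posterior_.sigma
        self.n_features_in_ = X.shape[1]
        return self

    def predict_draws(self, X):
        return self.posterior_.predict_draws(X)

    def predict(self, X):
        return self.predict_draws(X).mean(axis=0)

    def predictive_interval(self, X, level=0.95, rng=None):
        """Equal-tailed posterior-predictive interval per row (new-data noise
        included)."""
        rng = np.random.default_rng(0) if rng is None else rng
        f = self.predict_draws(X)
        eps = rng.standard_normal(f.shape) * self.posterior_.sigma[:, None]
        lo = (1.0 - level) / 2.0
        return np.quantile(f + eps, [lo, 1.0 - lo], axis=0)


class BartProbitClassifier(BaseEstimator, ClassifierMixin):
    """BART for binary outcomes via probit latent-normal augmentation.

    The latent error variance is fixed at 1; predictions pass through the
    standard normal CDF, so probabilities stay strictly inside (0, 1).
    The ``k``-scaled leaf prior covers +/-3 on the latent scale, and an
    offset at ``ndtri(mean(y))`` centres the forest on the base rate.
    """

    def __init__(self, n_trees=50, n_burn=250, n_draws=1000, alpha=0.95,
                 beta=2.0, k=2.0, p_grow=0.25, p_prune=0.25,
                 max_cutpoints=100, random_state=0):
        self.n_trees = n_trees
        self.n_burn = n_burn
        self.n_draws = n_draws
        self.alpha = alpha
        self.beta = beta
        self.k = k
        self.p_grow = p_grow
        self.p_prune = p_prune
        self.max_cutpoints = max_cutpoints
        self.random_state = random_state

    def fit(self, X, y):
        X, names = _prep_X(X)
        y = np.asarray(y)
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("y must be binary {0,1}")
        if uniq.size < 2:
            raise ValueError("y contains a single class; both classes required")
        y = y.astype(int)
        rng = np.random.default_rng(self.random_state)
        n = y.size

        offset = float(special.ndtri(np.clip(y.mean(), 1e-6, 1 - 1e-6)))
        sigma_mu = 3.0 / (self.k * np.sqrt(self.n_trees))
        z = np.zeros(n)
        smp = _Sampler(X, z, self.n_trees, self.alpha, self.beta, sigma_mu,
                       rng, self.p_grow, self.p_prune, self.max_cutpoints)
        smp.sigma2 = 1.0

        forests = []
        pos = y == 1
        for it in range(self.n_burn + self.n_draws):
            f = smp.total_fit + offset
            # truncated-normal latents: z > 0 where y=1, z < 0 where y=0
            u = rng.random(n)
            cdf0 = special.ndtr(-f)
            arg = np.where(pos, cdf0 + u * (1.0 - cdf0), u * cdf0)
            z = f + special.ndtri(np.clip(arg, 1e-12, 1.0 - 1e-12))
            zc = z - offset
            for t in range(self.n_trees):
                resid = zc - smp.total_fit + smp.tree_fit[t]
                smp.update_tree(t, resid)
            if it >= self.n_burn:
                forests.append(smp.snapshot())
        self.posterior_ = BartPosterior(forests, "probit", names, offset=offset)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_draws(self, X):
        """Per-draw event probabilities, shape (n_draws, n_rows)."""
        return self.posterior_.predict_draws(X)

    def predict_proba(self, X):
        p = self.predict_draws(X).mean(axis=0)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
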