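"""Sum-of-trees sampler: fit quality, calibration, posterior mechanics.

The Metropolis-Hastings moves were additionally validated against exact
posterior enumeration on one- and two-split tree spaces during
development; the frozen regression of that check is
``test_exact_posterior_on_enumerable_tree_space``.
"""

import numpy as np
import pytest
from scipy import stats

from cvdtraj.bart import BartPosterior, BartProbitClassifier, BartRegressor, _Sampler


@pytest.fixture(scope="module")
def step_data():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(500, 5))
    y = (X[:, 0] > 0).astype(float) + rng.normal(0, 0.1, 500)
    Xt = rng.normal(size=(400, 5))
    yt = (Xt[:, 0] > 0).astype(float)
    return X, y, Xt, yt


@pytest.fixture(scope="module")
def step_fit(step_data):
    X, y, _, _ = step_data
    return BartRegressor(n_trees=50, n_burn=100, n_draws=200, random_state=2).fit(X, y)


class TestContinuous:
    def test_constant_outcome_predicts_constant(self, rng):
        X = rng.normal(size=(60, 3))
        m = BartRegressor(n_trees=20, n_burn=20, n_draws=30, random_state=0).fit(
            X, np.full(60, 3.7)
        )
        assert np.abs(m.predict(X) - 3.7).max() < 1e-6

    def test_step_function_rmse_below_noise_margin(self, step_data, step_fit):
        # Bayes predictor achieves RMSE 0.1 (the noise SD); BART must come
        # close despite the discontinuity
        _, _, Xt, yt = step_data
        rmse = np.sqrt(np.mean((step_fit.predict(Xt) - yt) ** 2))
        assert rmse < 0.15

    def test_row_permutation_leaves_posterior_mean_stable(self, step_data):
        X, y, Xt, _ = step_data
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(y))
        a = BartRegressor(n_trees=30, n_burn=100, n_draws=200, random_state=4).fit(X, y)
        b = BartRegressor(n_trees=30, n_burn=100, n_draws=200, random_state=4).fit(
            X[perm], y[perm]
        )
        diff = np.abs(a.predict(Xt[:100]) - b.predict(Xt[:100]))
        assert diff.mean() < 0.02

    def test_sigma_trace_passes_stationarity_screen(self, step_fit):
        # no monotone drift across the retained draws: Kendall tau of the
        # trace against iteration index should be near zero
        trace = step_fit.sigma_trace_
        tau, _ = stats.kendalltau(np.arange(trace.size), trace)
        assert abs(tau) < 0.3
        # and the learned noise SD brackets the truth
        assert 0.07 < trace.mean() < 0.15

    def test_predictive_interval_coverage(self, rng):
        n = 500
        X = rng.uniform(-1, 1, size=(n, 3))
        f = np.sin(2 * X[:, 0]) + 0.5 * X[:, 1]
        y = f + rng.normal(0, 0.2, n)
        m = BartRegressor(n_trees=50, n_burn=100, n_draws=200, random_state=3).fit(X, y)
        Xt = rng.uniform(-1, 1, size=(300, 3))
        ft = np.sin(2 * Xt[:, 0]) + 0.5 * Xt[:, 1]
        yt = ft + rng.normal(0, 0.2, 300)
        lo, hi = m.predictive_interval(Xt, 0.95)
        cover = ((yt >= lo) & (yt <= hi)).mean()
        assert 0.85 <= cover <= 0.99

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            BartRegressor().fit(rng.normal(size=(5, 2)), np.zeros(5))


class TestProbit:
    def test_null_covariates_calibrated_to_base_rate(self, rng):
        # X carries no signal; standardized over points, predictions must
        # hover at the marginal event rate (pointwise wiggle reflects the
        # posterior's genuine uncertainty about cell rates)
        n = 1000
        y = (rng.random(n) < 0.3).astype(int)
        X = rng.normal(size=(n, 4))
        m = BartProbitClassifier(
            n_trees=50, n_burn=200, n_draws=300, random_state=3
        ).fit(X, y)
        p = m.predict_draws(rng.normal(size=(300, 4))).mean(axis=0)
        assert p.mean() == pytest.approx(0.3, abs=0.05)
        assert np.quantile(np.abs(p - 0.3), 0.9) < 0.15

    def test_separable_rule_recovered(self, rng):
        n = 1000
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] > 0).astype(int)
        m = BartProbitClassifier(
            n_trees=20, n_burn=100, n_draws=200, random_state=4
        ).fit(X, y)
        p = m.predict_draws(X).mean(axis=0)
        assert p[X[:, 0] > 0.5].mean() > 0.8
        assert p[X[:, 0] < -0.5].mean() < 0.2

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] + rng.normal(0, 1, 200) > 0).astype(int)
        m = BartProbitClassifier(
            n_trees=10, n_burn=30, n_draws=50, random_state=1
        ).fit(X, y)
        draws = m.predict_draws(X)
        assert np.all(draws > 0.0) and np.all(draws < 1.0)

    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            BartProbitClassifier().fit(rng.normal(size=(50, 2)), np.ones(50))


class TestPosterior:
    def test_prediction_matrix_shape_and_duplicates(self, step_data, step_fit):
        X, _, _, _ = step_data
        draws = step_fit.predict_draws(X[:50])
        assert draws.shape == (200, 50)
        dup = np.vstack([X[:3], X[:3]])
        d = step_fit.predict_draws(dup)
        np.testing.assert_array_equal(d[:, :3], d[:, 3:])

    def test_serialization_round_trip_bit_identical(self, step_data, step_fit):
        _, _, Xt, _ = step_data
        text = step_fit.posterior_.to_json()
        back = BartPosterior.from_json(text)
        np.testing.assert_array_equal(
            step_fit.predict_draws(Xt[:40]), back.predict_draws(Xt[:40])
        )

    def test_schema_mismatch_names_offenders(self, step_fit):
        import pandas as pd

        bad = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="x0"):
            step_fit.posterior_.predict_draws(bad)

    def test_same_seed_reproducible(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + rng.normal(0, 0.3, 100)
        a = BartRegressor(n_trees=10, n_burn=20, n_draws=30, random_state=7).fit(X, y)
        b = BartRegressor(n_trees=10, n_burn=20, n_draws=30, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.predict_draws(X), b.predict_draws(X))

    def test_sklearn_params_round_trip(self):
        m = BartRegressor(n_trees=17, k=3.0)
        assert m.get_params()["n_trees"] == 17
        m.set_params(n_trees=5)
        assert m.get_params()["n_trees"] == 5


class TestSamplerExactness:
    def test_exact_posterior_on_enumerable_tree_space(self):
        """One tree, one binary feature: the posterior over {stump, split}
        and the predictive means are available in closed form."""
        rng = np.random.default_rng(7)
        X = np.array([[0.0]] * 3 + [[1.0]] * 3)
        y = np.array([0.3, 0.1, 0.2, -0.25, -0.1, -0.4])
        tau2, sig2 = 0.05, 0.04
        alpha, beta = 0.95, 2.0

        def ml(r):
            n, s = len(r), r.sum()
            return (
                -n / 2 * np.log(2 * np.pi * sig2)
                - 0.5 * np.log1p(n * tau2 / sig2)
                - (r**2).sum() / (2 * sig2)
                + tau2 * s * s / (2 * sig2 * (sig2 + n * tau2))
            )

        lp0 = np.log(1 - alpha) + ml(y)
        lp1 = (
            np.log(alpha)
            + 2 * np.log(1 - alpha * 2.0**-beta)
            + ml(y[:3])
            + ml(y[3:])
        )
        w1 = 1.0 / (1.0 + np.exp(lp0 - lp1))

        def shrunk_mean(r):
            v = 1.0 / (1.0 / tau2 + len(r) / sig2)
            return v * r.sum() / sig2

        exact0 = (1 - w1) * shrunk_mean(y) + w1 * shrunk_mean(y[:3])

        smp = _Sampler(X, y, 1, alpha, beta, np.sqrt(tau2), rng)
        smp.sigma2 = sig2
        total0 = 0.0
        nsplit = 0
        N = 40_000
        for it in range(N + 2000):
            resid = y - smp.total_fit + smp.tree_fit[0]
            smp.update_tree(0, resid)
            if it >= 2000:
                total0 += smp.total_fit[0]
                nsplit += 0 if smp.trees[0].is_leaf else 1
        assert nsplit / N == pytest.approx(w1, abs=0.01)
        assert total0 / N == pytest.approx(exact0, abs=0.01)
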