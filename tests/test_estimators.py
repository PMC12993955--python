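"""Tests for the static OLS and dynamic (Kalman) average-effect estimators."""

import numpy as np
import pytest

from devsens import estimators as est
from devsens import genetics as gen
from devsens import population as pop


def make_series(codes, observed, times=None):
    codes = np.asarray(codes)
    observed = np.asarray(observed, float)
    if observed.ndim == 2:
        observed = observed[:, :, None]
    if times is None:
        times = np.arange(observed.shape[1], dtype=float)
    return pop.PhenotypeSeries(
        times=times,
        observed=observed,
        true_states=observed,
        genotypes=gen.GenotypeMatrix(codes=codes),
        env_params=np.zeros((codes.shape[0], 0)),
        lam=np.zeros((codes.shape[0], 0)),
    )


class TestStaticEstimator:
    def test_noise_free_single_locus_recovers_additive_value(self):
        bundle = pop.scenario_single_locus(gamma=0.02)
        trio = gen.genotypic_values(
            bundle.system, bundle.x0, bundle.grid, bundle.loci[0], bundle.lam_ref
        )
        curves = gen.effect_curves(*trio, freq_B=0.5)
        static = est.static_average_effects(bundle.series, trait_index=0)
        np.testing.assert_allclose(static.alpha[:, 0], curves.a[:, 0], atol=1e-10)
        # residuals carry exactly the dominance deviation, nothing more:
        # each genotype class sits at its fitted value +/- its share of d
        assert static.sigma2_eps.max() == pytest.approx(
            (curves.d[:, 0] ** 2).max() * 20 / 4 / 18, rel=1e-6
        )

    def test_multi_locus_small_effects_match_sensitivity_truth(self, sens_toggle):
        bundles = pop.scenario_estimation(
            512, 0.0, 0.0, 1, seed=4, gamma_sd=1e-3, sens=sens_toggle
        )
        b = bundles[0]
        static = est.static_average_effects(b.series, trait_index=0)
        truth = b.alpha_true[:, 0, :]
        # noise-free: deviation from gamma*s is the Taylor remainder O(gamma^2)
        assert np.abs(static.alpha[1:] - truth[1:]).max() < 1e-4

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(-1, 2, size=(40, 3))
        observed = rng.normal(size=(40, 6))
        a = est.static_average_effects(make_series(codes, observed))
        perm = rng.permutation(40)
        b = est.static_average_effects(make_series(codes[perm], observed[perm]))
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-10)
        np.testing.assert_allclose(a.se, b.se, atol=1e-10)

    def test_underdetermined_design_rejected(self):
        codes = np.array([[1, 0], [0, 1], [-1, 1]])
        with pytest.raises(ValueError, match="individuals"):
            est.static_average_effects(make_series(codes, np.zeros((3, 2))))

    def test_collinear_loci_named(self):
        rng = np.random.default_rng(1)
        base = rng.integers(-1, 2, size=(30, 1))
        codes = np.hstack([base, base, rng.integers(-1, 2, size=(30, 1))])
        with pytest.raises(ValueError, match=r"collinear loci: \[0, 1\]"):
            est.static_average_effects(make_series(codes, np.zeros((30, 4))))


def grid_filter_oracle(y, R, Q, x_grid):
    """Brute-force Bayesian filter on a dense state grid (random-walk model,
    Gaussian observation); returns posterior means per time."""
    dx = x_grid[1] - x_grid[0]
    # tight prior at zero, matching the filter initialization
    prior = np.exp(-0.5 * x_grid**2 / 1e-12)
    trans = np.exp(-0.5 * (x_grid[None, :] - x_grid[:, None]) ** 2 / Q)
    means = []
    for t, (yt, rt) in enumerate(zip(y, R)):
        if t > 0:
            prior = trans.T @ prior * dx
        like = np.exp(-0.5 * (yt - x_grid) ** 2 / rt)
        post = prior * like
        post /= post.sum() * dx
        means.append(np.sum(x_grid * post) * dx)
        prior = post
    return np.array(means)


class TestKalman:
    def make_static(self, y, se):
        y = np.asarray(y, float)[:, None]
        se = np.broadcast_to(np.asarray(se, float)[:, None], y.shape).copy()
        T = y.shape[0]
        return est.StaticEstimate(
            times=np.arange(T, dtype=float), alpha=y, se=se,
            mu=np.zeros(T), sigma2_eps=np.ones(T),
        )

    def test_infinite_process_noise_tracks_observations(self):
        static = self.make_static([0.0, -1.0, 2.0, 0.3], [0.1, 0.1, 0.1, 0.1])
        out = est.kalman_average_effects(static, est.KalmanConfig(q_process=1e12))
        # the filter pins t0 at zero (zero initial sensitivity); from t1 on
        # an enormous Q makes the gain ~1 and the filter just tracks
        np.testing.assert_allclose(out.alpha[1:], static.alpha[1:], rtol=1e-6)

    def test_zero_process_noise_gives_precision_weighted_mean(self):
        rng = np.random.default_rng(2)
        truth = 0.7
        se = np.full(30, 0.2)
        y = truth + rng.normal(0, 0.2, 30)
        static = self.make_static(y, se)
        out = est.kalman_average_effects(
            static, est.KalmanConfig(q_process=0.0, init_var=1e6)
        )
        # with a flat prior and Q=0 the filter is the running sample mean
        running_mean = np.cumsum(y) / np.arange(1, 31)
        np.testing.assert_allclose(out.alpha[:, 0], running_mean, rtol=1e-4)

    def test_matches_grid_filter_oracle(self):
        rng = np.random.default_rng(3)
        Q, R = 0.04, 0.09
        truth = np.cumsum(rng.normal(0, np.sqrt(Q), 8))
        truth[0] = 0.0
        y = truth + rng.normal(0, np.sqrt(R), 8)
        y[0] = 0.0
        static = self.make_static(y, np.full(8, np.sqrt(R)))
        out = est.kalman_average_effects(static, est.KalmanConfig(q_process=Q))
        x_grid = np.linspace(-6, 6, 4001)
        oracle = grid_filter_oracle(y, np.full(8, R), Q, x_grid)
        np.testing.assert_allclose(out.alpha[:, 0], oracle, atol=1e-6)

    def test_filtered_variance_shrinks_with_observations(self):
        static = self.make_static(np.zeros(20), np.full(20, 0.5))
        out = est.kalman_average_effects(
            static, est.KalmanConfig(q_process=0.0, init_var=10.0)
        )
        assert np.all(np.diff(out.var[:, 0]) <= 1e-15)

    def test_nonfinite_observations_rejected(self):
        static = self.make_static([0.0, np.nan, 1.0], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="non-finite"):
            est.kalman_average_effects(static)

    def test_smoother_reduces_error_on_random_walk(self):
        rng = np.random.default_rng(9)
        Q, R = 0.01, 0.25
        truth = np.cumsum(rng.normal(0, np.sqrt(Q), size=(60, 1)), axis=0)
        y = truth + rng.normal(0, np.sqrt(R), size=(60, 1))
        static = est.StaticEstimate(
            times=np.arange(60.0), alpha=y, se=np.full((60, 1), np.sqrt(R)),
            mu=np.zeros(60), sigma2_eps=np.ones(60),
        )
        filt = est.kalman_average_effects(static, est.KalmanConfig(q_process=Q))
        smth = est.kalman_average_effects(static, est.KalmanConfig(q_process=Q, smooth=True))
        assert np.mean((smth.alpha - truth) ** 2) < np.mean((filt.alpha - truth) ** 2)


class TestRelativeError:
    def test_exact_estimate_and_doubling(self):
        truth = np.arange(1.0, 13.0).reshape(4, 3)
        assert est.relative_error(truth, truth).mean == 0.0
        assert est.relative_error(2 * truth, truth).mean == pytest.approx(1.0)

    def test_initial_time_excluded(self):
        truth = np.vstack([np.zeros(2), np.ones((3, 2))])
        out = est.relative_error(truth + 0.1, truth)
        assert out.per_cell.shape == (3, 2)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            est.relative_error(np.ones((3, 2)), np.zeros((3, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            est.relative_error(np.ones((3, 2)), np.ones((2, 3)))
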