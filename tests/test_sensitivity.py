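"""Unit and property tests for sensitivity computation and angle statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from devsens import dynamics as dyn
from devsens import sensitivity as sens


@pytest.fixture(scope="module")
def quad_toy():
    """dx/dt = lam^2 - x: at lam*=0, s = 0 and s1(t) = 2(1 - exp(-t))."""
    return dyn.ODESystem(
        n_states=1,
        n_params=1,
        rhs=lambda t, x, lam: np.array([lam[0] ** 2 - x[0]]),
        name="quad_toy",
    )


class TestVariational:
    def test_zero_initial_sensitivity(self, sens_toggle):
        np.testing.assert_array_equal(sens_toggle.s[0], 0.0)

    def test_linear_relaxation_closed_form(self, linear_relax):
        grid = dyn.TimeGrid(0, 10, 0.5)
        ss = sens.sensitivities_variational(linear_relax, [0.0], [0.0], grid)
        np.testing.assert_allclose(
            ss.s[:, 0, 0], 1.0 - np.exp(-grid.times), rtol=1e-7, atol=1e-9
        )

    def test_reference_trajectory_is_attached(self, sens_toggle, toggle, grid50):
        traj = dyn.integrate(toggle, [0, 0], [0, 0], grid50)
        np.testing.assert_allclose(
            sens_toggle.trajectory.states, traj.states, rtol=1e-7, atol=1e-10
        )


class TestFiniteDifference:
    def test_parameter_independent_system_has_zero_sensitivity(self):
        system = dyn.ODESystem(
            n_states=1, n_params=1, rhs=lambda t, x, lam: -x, name="no_lam"
        )
        with pytest.warns(UserWarning, match="solver tolerance"):
            ss = sens.sensitivities_fd(system, [1.0], [0.0], dyn.TimeGrid(0, 5, 1))
        np.testing.assert_allclose(ss.s, 0.0, atol=1e-6)

    def test_matches_variational_on_toggle(self, toggle, grid50, sens_toggle):
        fd = sens.sensitivities_fd(toggle, [0, 0], [0, 0], grid50, dlam=1e-5)
        rel = np.abs(fd.s[1:] - sens_toggle.s[1:]) / np.abs(sens_toggle.s[1:])
        assert rel.max() < 1e-3

    def test_step_halving_is_converged(self, toggle):
        grid = dyn.TimeGrid(0, 20, 1)
        a = sens.sensitivities_fd(toggle, [0, 0], [0, 0], grid, dlam=1e-4)
        b = sens.sensitivities_fd(toggle, [0, 0], [0, 0], grid, dlam=5e-5)
        rel = np.abs(a.s[1:] - b.s[1:]) / np.abs(b.s[1:])
        assert rel.max() < 1e-4

    def test_linearity_in_perturbation(self, toggle, grid50, sens_toggle):
        """Trajectory shift minus gamma*s is a second-order remainder:
        halving gamma shrinks it about fourfold."""
        ref = sens_toggle.trajectory.states
        errs = []
        for gamma in (2e-3, 1e-3):
            pert = dyn.integrate(toggle, [0, 0], [gamma, 0.0], grid50)
            remainder = pert.states - ref - gamma * sens_toggle.s[:, :, 0]
            errs.append(np.linalg.norm(remainder))
        assert 3.0 < errs[0] / errs[1] < 5.0


class TestSecondOrder:
    def test_linear_in_lambda_system_is_zero(self, linear_relax):
        so = sens.second_order_fd(linear_relax, [0.0], [0.0], dyn.TimeGrid(0, 5, 1))
        np.testing.assert_allclose(so.s1, 0.0, atol=1e-5)

    def test_quadratic_toy_closed_form(self, quad_toy):
        grid = dyn.TimeGrid(0, 10, 1)
        so = sens.second_order_fd(quad_toy, [0.0], [0.0], grid)
        np.testing.assert_allclose(
            so.s1[:, 0, 0], 2.0 * (1.0 - np.exp(-grid.times)), rtol=1e-5, atol=1e-7
        )


class TestRegression:
    def test_recovers_exact_linear_map(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(3, 2))  # traits x params
        draws = rng.normal(0, 1e-2, size=(40, 2))
        times = np.array([0.0, 1.0])
        Y = np.stack([np.zeros((40, 3)), draws @ S.T], axis=1)  # (R, T, n)
        ss = sens.sensitivities_regression(Y, draws, np.zeros(2), times=times)
        np.testing.assert_allclose(ss.s[1], S, rtol=1e-10, atol=1e-12)

    def test_matches_variational_on_toggle(self, toggle, grid50, sens_toggle):
        rng = np.random.default_rng(7)
        draws = rng.normal(0.0, 1e-3, size=(200, 2))
        Y = dyn.integrate_batch(toggle, np.zeros((200, 2)), draws, grid50)
        ss = sens.sensitivities_regression(Y, draws, np.zeros(2), times=grid50.times)
        rel = np.abs(ss.s[-1] - sens_toggle.s[-1]) / np.abs(sens_toggle.s[-1])
        assert rel.max() < 0.02

    def test_duplicated_runs_leave_estimate_unchanged(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0, 1e-2, size=(10, 2))
        Y = rng.normal(size=(10, 3, 2))
        a = sens.sensitivities_regression(Y, draws, np.zeros(2), times=np.arange(3.0))
        b = sens.sensitivities_regression(
            np.concatenate([Y, Y]), np.concatenate([draws, draws]),
            np.zeros(2), times=np.arange(3.0),
        )
        np.testing.assert_allclose(a.s, b.s, rtol=1e-9, atol=1e-12)

    def test_collinear_parameters_are_reported(self):
        draws = np.zeros((10, 2))
        draws[:, 0] = np.linspace(-1, 1, 10)
        draws[:, 1] = 2 * draws[:, 0]
        Y = np.zeros((10, 2, 1))
        with pytest.raises(ValueError, match="collinear"):
            sens.sensitivities_regression(Y, draws, np.zeros(2), times=np.arange(2.0))

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError, match="runs"):
            sens.sensitivities_regression(
                np.zeros((3, 2, 1)), np.zeros((3, 2)), np.zeros(2), times=np.arange(2.0)
            )


class TestAngle:
    def test_reference_cases(self):
        assert sens.angle([1, 0], [1, 0]) == 0.0
        assert sens.angle([1, 0], [0, 1]) == pytest.approx(90.0)
        assert sens.angle([1, 0], [-1, 0]) == pytest.approx(180.0)
        assert sens.angle([1, 0], [-1, 0], convention="axial") == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sens.angle([0, 0], [1, 0])

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.floats(0.01, 100.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, u, v, c):
        u, v = np.asarray(u), np.asarray(v)
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        for conv in ("directed", "axial"):
            assert sens.angle(u, v, conv) == pytest.approx(
                sens.angle(c * u, v, conv), abs=1e-8
            )

    def test_pairwise_angles_skip_t0_and_env_alignment(self, sens_env):
        report = sens.pairwise_angles(sens_env, convention="axial")
        assert report.times[0] == 1.0
        j23 = report.pairs.index((1, 2))
        # lam2 and lam3 force the same gene: collinear throughout development
        assert report.angle_by_time[:, j23].max() < 1.0


class TestRandomAngleNull:
    def test_dim2_is_uniform(self):
        draws = sens.random_angle_null(2, 50_000, seed=11)
        ks = stats.kstest(draws, stats.uniform(loc=0, scale=180).cdf)
        assert ks.statistic < 0.01

    def test_dim4_mean_and_closed_form_cdf(self):
        draws = sens.random_angle_null(4, 100_000, seed=12)
        assert abs(draws.mean() - 90.0) < 0.5
        ks = stats.kstest(draws, lambda x: sens.angle_cdf(x, 4))
        assert ks.statistic < 0.01

    def test_pdf_normalization_and_cdf_limits(self):
        theta = np.linspace(0, 180, 20_001)
        for dim in (2, 3, 4, 7):
            mass = np.trapezoid(sens.angle_pdf(theta, dim), theta)
            assert mass == pytest.approx(1.0, abs=1e-6)
            assert sens.angle_cdf(np.array([0.0]), dim)[0] == 0.0
            assert sens.angle_cdf(np.array([180.0]), dim)[0] == pytest.approx(1.0)
            assert sens.angle_cdf(np.array([90.0]), dim)[0] == pytest.approx(0.5)

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            sens.random_angle_null(1, 10)
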