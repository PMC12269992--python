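"""Linearized Hopf machinery: Jacobian, Lyapunov statistics, simulation, fitting."""

import numpy as np
import pytest

from brainarrow.errors import InstabilityError, ParameterError
from brainarrow.hopf import (
    HopfParameters,
    build_jacobian,
    empirical_statistics,
    estimate_frequencies,
    fit_cohort,
    fit_gec,
    model_statistics,
    node_strengths,
    simulate_hopf,
    stationary_covariance,
)
from brainarrow.signal_io import CouplingMatrix

from helpers import as_preprocessed, mark_preprocessed


def params_n(n, a=-0.02, omega=0.3, sigma=0.02, tr=2.2):
    return HopfParameters(np.full(n, a), np.full(n, omega), sigma, tr)


class TestJacobian:
    def test_single_node_block_form(self):
        J = build_jacobian(np.zeros((1, 1)), params_n(1, omega=0.3))
        np.testing.assert_allclose(J, [[-0.02, -0.3], [0.3, -0.02]])

    def test_diffusive_coupling_always_stable(self, rng):
        # rows of A sum to a < 0 beyond diagonal coupling -> Gershgorin-stable
        n = 8
        C = np.abs(rng.standard_normal((n, n))) * 0.3
        np.fill_diagonal(C, 0)
        J = build_jacobian(C, params_n(n))
        ev = np.linalg.eigvals(J)
        assert ev.real.max() < 0

    def test_supercritical_uncoupled_unstable(self):
        with pytest.raises(InstabilityError):
            build_jacobian(np.zeros((2, 2)), params_n(2, a=+0.01))


class TestStationaryCovariance:
    def test_single_node_closed_form(self):
        # J Sigma + Sigma J^T = -sigma^2 I with c = -sigma^2/(2a)
        J = build_jacobian(np.zeros((1, 1)), params_n(1, omega=1.7))
        S = stationary_covariance(J, 0.02)
        np.testing.assert_allclose(S, 0.01 * np.eye(2), atol=1e-10)

    def test_sigma_scaling_is_quadratic(self, rng):
        n = 4
        C = np.abs(rng.standard_normal((n, n))) * 0.1
        np.fill_diagonal(C, 0)
        J = build_jacobian(C, params_n(n))
        S1 = stationary_covariance(J, 0.02)
        S2 = stationary_covariance(J, 0.04)
        np.testing.assert_allclose(S2, 4 * S1, rtol=1e-10)

    def test_result_is_spd(self, rng):
        n = 5
        C = np.abs(rng.standard_normal((n, n))) * 0.1
        np.fill_diagonal(C, 0)
        J = build_jacobian(C, params_n(n))
        S = stationary_covariance(J, 0.02)
        assert np.linalg.eigvalsh(S).min() > 0


class TestModelStatistics:
    def test_uncoupled_closed_forms(self):
        p = params_n(3, a=-0.02, omega=0.25, tr=2.2)
        ms = model_statistics(np.zeros((3, 3)), p, lag=2.2)
        np.testing.assert_allclose(ms.fc, np.eye(3), atol=1e-12)
        expected = np.exp(-0.02 * 2.2) * np.cos(0.25 * 2.2)
        np.testing.assert_allclose(np.diag(ms.csv), expected, atol=1e-10)
        off = ms.csv[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-10)

    def test_zero_lag_reduces_to_fc(self, rng):
        n = 4
        C = np.abs(rng.standard_normal((n, n))) * 0.1
        np.fill_diagonal(C, 0)
        ms = model_statistics(C, params_n(n), lag=0.0)
        np.testing.assert_allclose(ms.csv, ms.fc, atol=1e-12)

    def test_linear_approximation_matches_nonlinear_simulation(self):
        # a = -0.02, weak coupling, weak noise: the linear approximation's
        # validity regime. (At sigma = 0.02 the cubic saturation biases FC
        # by up to ~0.1 per element; see the methods note.)
        n = 4
        C = np.zeros((n, n))
        for i in range(n - 1):
            C[i + 1, i] = 0.18
            C[i, i + 1] = 0.12
        p = HopfParameters(np.full(n, -0.02), np.full(n, 0.3), 0.01, tr=2.0)
        ms = model_statistics(C, p, lag=2.0)
        ts = simulate_hopf(C, p, duration=60_000, dt=0.05, seed=11,
                           burn_in=200)
        emp = empirical_statistics(as_preprocessed(ts.values, tr=2.0), 1)
        assert np.abs(emp.fc - ms.fc).max() < 0.05
        assert np.abs(emp.csv - ms.csv).max() < 0.05

    def test_model_reproduces_empirical_asymmetry_signs(self):
        # orientation sanity: the model's lagged-correlation asymmetry must
        # match simulated data in sign, and flip under deliberate transposition
        n = 5
        rng = np.random.default_rng(5)
        C = np.where(rng.random((n, n)) < 0.5, rng.uniform(0.05, 0.2, (n, n)), 0)
        np.fill_diagonal(C, 0)
        p = HopfParameters(np.full(n, -0.05), np.full(n, 0.2), 0.02, tr=2.0)
        ms = model_statistics(C, p, lag=2.0)
        ts = simulate_hopf(C, p, duration=40_000, dt=0.05, seed=3, burn_in=200,
                           cubic=False)
        emp = empirical_statistics(mark_preprocessed(as_preprocessed(ts.values, tr=2.0)), 1)
        asym_emp = emp.csv - emp.csv.T
        asym_mod = ms.csv - ms.csv.T
        big = np.abs(asym_emp) > 0.05
        assert big.any()
        agree = np.sign(asym_emp[big]) == np.sign(asym_mod[big])
        assert agree.mean() >= 0.8
        agree_t = np.sign(asym_emp[big]) == np.sign(asym_mod.T[big])
        assert agree_t.mean() <= 0.2


class TestEmpiricalStatistics:
    def test_shifted_pair_has_directed_lagged_correlation(self, rng):
        x = rng.standard_normal(500)
        lag = 3
        y = np.roll(x, lag)  # y(t) = x(t - lag) -> x leads y
        ts = as_preprocessed(np.column_stack([x, y]))
        emp = empirical_statistics(ts, lag)
        assert emp.csv[0, 1] > 0.95
        assert abs(emp.csv[1, 0]) < 0.3

    def test_duplicated_series_fc_is_one(self, rng):
        x = rng.standard_normal(200)
        emp = empirical_statistics(as_preprocessed(np.column_stack([x, x])), 1)
        assert emp.fc[0, 1] == pytest.approx(1.0)

    def test_zero_lag_matches_fc_up_to_normalization(self, rng):
        ts = as_preprocessed(rng.standard_normal((100, 3)))
        emp = empirical_statistics(ts, 0)
        np.testing.assert_allclose(emp.csv, emp.fc, atol=1e-10)


class TestEstimateFrequencies:
    def test_oscillating_node_recovered(self):
        tr = 2.2
        t = np.arange(400) * tr
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal(400)
        y = rng.standard_normal(400)
        ts = as_preprocessed(np.column_stack([x, y]), tr=tr)
        omega = estimate_frequencies([ts], (0.008, 0.08))
        assert omega[0] == pytest.approx(2 * np.pi * 0.05, rel=0.05)

    def test_white_noise_peak_inside_band(self, rng):
        ts = as_preprocessed(rng.standard_normal((300, 3)), tr=2.2)
        omega = estimate_frequencies([ts], (0.008, 0.08))
        f = omega / (2 * np.pi)
        assert np.all((f >= 0.008) & (f <= 0.08))

    def test_two_subjects_average_between_peaks(self):
        tr = 2.2
        t = np.arange(512) * tr
        a = as_preprocessed(np.sin(2 * np.pi * 0.04 * t)[:, None], tr=tr)
        b = as_preprocessed(np.sin(2 * np.pi * 0.06 * t)[:, None], tr=tr)
        omega = estimate_frequencies([a, b], (0.008, 0.08))
        f = omega[0] / (2 * np.pi)
        assert 0.035 <= f <= 0.065

    def test_band_outside_nyquist_rejected(self, rng):
        ts = as_preprocessed(rng.standard_normal((300, 2)), tr=2.2)
        with pytest.raises(ParameterError):
            estimate_frequencies([ts], (0.008, 0.5))


class TestSimulateHopf:
    def test_same_seed_identical(self):
        p = params_n(3, tr=1.0)
        C = np.zeros((3, 3))
        a = simulate_hopf(C, p, duration=150, dt=0.1, seed=9)
        b = simulate_hopf(C, p, duration=150, dt=0.1, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_linear_variance_matches_lyapunov(self):
        # small omega so the Euler step is accurate at this dt
        p = HopfParameters(np.array([-0.02]), np.array([0.03]), 0.02, tr=1.0)
        ts = simulate_hopf(np.zeros((1, 1)), p, duration=100_000, dt=0.1,
                           seed=4, cubic=False, burn_in=500)
        assert ts.values.var() == pytest.approx(0.01, rel=0.10)

    def test_supercritical_limit_cycle_frequency(self):
        f0 = 0.05
        p = HopfParameters(np.array([0.05]), np.array([2 * np.pi * f0]),
                           1e-8, tr=1.0)
        ts = simulate_hopf(np.zeros((1, 1)), p, duration=2000, dt=0.05,
                           seed=0, burn_in=300)
        x = ts.values[:, 0]
        spec = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(x.size, d=1.0)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(f0, rel=0.02)

    def test_short_duration_rejected(self):
        p = params_n(2, tr=2.2)
        with pytest.raises(ParameterError, match="duration"):
            simulate_hopf(np.zeros((2, 2)), p, duration=50, seed=0)


class TestFitGec:
    def test_zero_coupling_is_fixed_point(self):
        n = 6
        p = params_n(n, omega=0.25)
        emp = model_statistics(np.zeros((n, n)), p, lag=2.2)
        mask = np.ones((n, n)) - np.eye(n)
        fit = fit_gec(emp, mask, p, lag=2.2, max_iter=2000)
        assert fit.coupling.weights.max() < 0.01

    def test_truth_init_does_not_move(self, rng):
        n = 6
        C = np.where(rng.random((n, n)) < 0.5, rng.uniform(0.02, 0.1, (n, n)), 0)
        np.fill_diagonal(C, 0)
        p = params_n(n, omega=0.25)
        emp = model_statistics(C, p, lag=2.2)
        fit = fit_gec(emp, (C > 0).astype(float), p, lag=2.2, init=C,
                      max_iter=300)
        assert fit.fit_error_trace[0] == pytest.approx(
            fit.fit_error_trace.min(), abs=1e-9)
        assert np.abs(fit.coupling.weights - C).max() < 1e-3

    def test_error_never_worse_than_initialization(self, rng):
        n = 6
        C = np.where(rng.random((n, n)) < 0.5, rng.uniform(0.02, 0.1, (n, n)), 0)
        np.fill_diagonal(C, 0)
        p = params_n(n, omega=0.25)
        emp = model_statistics(C, p, lag=2.2)
        fit = fit_gec(emp, (C > 0).astype(float), p, lag=2.2, max_iter=500)
        assert fit.fit_error_trace.min() <= fit.fit_error_trace[0]

    def test_region_reordering_invariance(self, rng):
        n = 5
        C = np.where(rng.random((n, n)) < 0.6, rng.uniform(0.02, 0.1, (n, n)), 0)
        np.fill_diagonal(C, 0)
        p = params_n(n, omega=0.25)
        perm = rng.permutation(n)
        emp = model_statistics(C, p, lag=2.2)
        fit = fit_gec(emp, (C > 0).astype(float), p, lag=2.2, max_iter=400)
        emp_p = model_statistics(C[np.ix_(perm, perm)], p, lag=2.2)
        fit_p = fit_gec(emp_p, (C[np.ix_(perm, perm)] > 0).astype(float), p,
                        lag=2.2, max_iter=400)
        np.testing.assert_allclose(
            fit_p.coupling.weights,
            fit.coupling.weights[np.ix_(perm, perm)], atol=1e-8)


class TestFitCohort:
    def test_identical_subjects_match_group_at_fixed_point(self, rng):
        # group pretraining initialized at the self-consistent solution: the
        # misfit is zero, so group and every individual fit coincide exactly
        n = 5
        C = np.where(rng.random((n, n)) < 0.6, rng.uniform(0.02, 0.08, (n, n)), 0)
        np.fill_diagonal(C, 0)
        p = params_n(n, omega=0.25)
        stats = model_statistics(C, p, lag=2.2)
        group, models = fit_cohort([stats, stats, stats], (C > 0).astype(float),
                                   p, 2.2, group_max_iter=500,
                                   subject_max_iter=500, init=C)
        for m in models:
            assert np.abs(m.coupling.weights - group.coupling.weights).max() < 1e-6

    def test_identical_subjects_have_identical_fits(self, rng):
        # away from the fixed point the continuation drifts identically for
        # every subject; fits are bit-identical and improve on the group error
        n = 5
        C = np.where(rng.random((n, n)) < 0.6, rng.uniform(0.02, 0.08, (n, n)), 0)
        np.fill_diagonal(C, 0)
        p = params_n(n, omega=0.25)
        stats = model_statistics(C, p, lag=2.2)
        group, models = fit_cohort([stats, stats], (C > 0).astype(float),
                                   p, 2.2, group_max_iter=800,
                                   subject_max_iter=400)
        np.testing.assert_array_equal(models[0].coupling.weights,
                                      models[1].coupling.weights)
        for m in models:
            assert m.fit_error_trace.min() <= group.fit_error_trace.min() + 1e-12

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            fit_cohort([], np.ones((2, 2)), params_n(2), 2.2)


class TestNodeStrengths:
    def test_single_edge(self):
        C = np.array([[0.0, 0.7], [0.0, 0.0]])
        np.testing.assert_allclose(node_strengths(C), [0.7, 0.7])

    def test_matches_brute_force(self, rng):
        C = np.abs(rng.standard_normal((5, 5)))
        expected = [C[:, i].sum() + C[i, :].sum() for i in range(5)]
        np.testing.assert_allclose(node_strengths(C), expected)
        assert node_strengths(C).sum() == pytest.approx(2 * C.sum())
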