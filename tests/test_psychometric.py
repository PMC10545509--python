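"""Psychometric model: prediction, likelihood, fitting, threshold and slope."""

import math

import numpy as np
import pytest

import vocometric as vm
from vocometric.psychometric import FitOptions


class TestPredict:
    def test_floor_at_one_channel_equals_guess_rate(self):
        assert vm.predict_pcorrect(0.0, 1.5, 3.0, gamma=0.1, lam=0.05) == \
            pytest.approx(0.1)

    def test_ceiling_approaches_one_minus_lapse(self):
        p = vm.predict_pcorrect(50.0, 1.5, 3.0, gamma=0.1, lam=0.05)
        assert p == pytest.approx(0.95, abs=1e-9)

    def test_weibull_value_at_scale(self):
        # gamma = lam = 0, x = alpha: p = 1 - 1/e
        p = vm.predict_pcorrect(1.7, 1.7, 4.0)
        assert p == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_monotone_in_x(self):
        x = np.linspace(0, 5, 200)
        p = vm.predict_pcorrect(x, 1.5, 2.5, gamma=0.04, lam=0.02)
        assert np.all(np.diff(p) >= 0)

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError):
            vm.predict_pcorrect(1.0, -1.0, 2.0)


class TestNegLogLikelihood:
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 4.585])
    n = np.full(6, 12.0)

    def _brute_force_binomial(self, theta, x, k, n):
        alpha, beta, gamma, lam, _ = theta
        total = 0.0
        for xi, ki, ni in zip(x, k, n):
            p = gamma + (1 - gamma - lam) * (1 - math.exp(-((xi / alpha) ** beta))) \
                if xi > 0 else gamma
            p = min(max(p, 1e-9), 1 - 1e-9)
            mass = math.comb(int(ni), int(ki)) * p**ki * (1 - p) ** (ni - ki)
            total -= math.log(mass)
        return total

    def test_matches_brute_force_binomial_summation(self):
        theta = (1.65, 3.0, 0.04, 0.02, 0.0)
        p = vm.predict_pcorrect(self.x, *theta[:4])
        k = np.round(self.n * p)
        expected = self._brute_force_binomial(theta, self.x, k, self.n)
        assert vm.neg_log_likelihood(theta, self.x, k, self.n) == \
            pytest.approx(expected, rel=1e-12)

    def test_beta_binomial_converges_to_binomial_as_eta_vanishes(self):
        k = np.array([1, 3, 7, 11, 12, 12])
        nll0 = vm.neg_log_likelihood((1.65, 3.0, 0.04, 0.02, 0.0), self.x, k, self.n)
        nll_eps = vm.neg_log_likelihood((1.65, 3.0, 0.04, 0.02, 1e-4), self.x, k, self.n)
        assert abs(nll_eps - nll0) < 1e-4

    def test_likelihood_additivity_under_duplication(self):
        k = np.array([1, 3, 7, 11, 12, 12])
        theta = (1.65, 3.0, 0.02, 0.02, 0.1)
        single = vm.neg_log_likelihood(theta, self.x, k, self.n)
        double = vm.neg_log_likelihood(theta, np.tile(self.x, 2), np.tile(k, 2),
                                       np.tile(self.n, 2))
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_rejects_eta_outside_unit_interval(self):
        k = np.array([1, 3, 7, 11, 12, 12])
        with pytest.raises(ValueError):
            vm.neg_log_likelihood((1.65, 3.0, 0.0, 0.0, 1.0), self.x, k, self.n)


class TestThresholdAndSlope:
    def test_closed_form_threshold_sharpens_to_scale(self):
        # gamma = lam = 0: x50 = alpha * (ln 2)**(1/beta); large beta -> 2**alpha
        alpha = np.log2(3.14)
        assert vm.threshold_50(alpha, 2.0) == \
            pytest.approx(2 ** (alpha * math.log(2) ** 0.5), rel=1e-12)
        assert vm.threshold_50(alpha, 1000.0) == pytest.approx(3.14, abs=0.01)

    def test_pathological_guess_rate_floors_at_one_channel(self):
        assert vm.threshold_50(1.5, 3.0, gamma=0.499999) == \
            pytest.approx(1.0, abs=0.02)

    def test_lapse_above_half_is_undefined_not_numeric_failure(self):
        with pytest.raises(vm.UndefinedThresholdError):
            vm.threshold_50(1.5, 3.0, lam=0.6)

    @pytest.mark.parametrize("gamma,lam", [(0.0, 0.0), (0.04, 0.02), (0.0, 0.45)])
    def test_slope_matches_central_finite_difference(self, gamma, lam):
        alpha, beta = 1.65, 4.0
        thr = vm.threshold_50(alpha, beta, gamma, lam)
        x50, h = np.log2(thr), 1e-5
        fd = (vm.predict_pcorrect(x50 + h, alpha, beta, gamma, lam)
              - vm.predict_pcorrect(x50 - h, alpha, beta, gamma, lam)) / (2 * h)
        assert vm.slope_at_threshold(alpha, beta, gamma, lam) == \
            pytest.approx(fd, abs=1e-6)

    def test_steeper_shape_gives_steeper_slope(self):
        s1 = vm.slope_at_threshold(1.65, 4.0)
        s2 = vm.slope_at_threshold(1.65, 8.0)
        assert s2 > s1

    def test_threshold_slope_parameterisation_roundtrip(self):
        m, s, gamma, lam = 3.14, 1.08, 0.04, 0.02
        alpha, beta = vm.weibull_from_threshold_slope(m, s, gamma, lam)
        assert vm.threshold_50(alpha, beta, gamma, lam) == pytest.approx(m, rel=1e-10)
        assert vm.slope_at_threshold(alpha, beta, gamma, lam) == \
            pytest.approx(s, rel=1e-10)


class TestFit:
    def test_recovers_threshold_from_noiseless_large_n_data(self):
        """Self-consistency: k = round(n p) at n = 1200/level pins the MLE."""
        alpha, beta, gamma, lam = vm.weibull_from_threshold_slope(3.14, 1.08,
                                                                  0.04, 0.0) + (0.04, 0.0)
        x = np.log2(np.arange(1, 25, dtype=float))
        n = np.full(24, 1200.0)
        k = np.round(n * vm.predict_pcorrect(x, alpha, beta, gamma, lam))
        fit = vm.fit_psychometric(x, k, n)
        assert fit.threshold == pytest.approx(3.14, rel=0.02)

    def test_optimizer_dominates_exhaustive_grid(self):
        """The MLE's nll is at least as good as a dense 4-D grid's (eta = 0)."""
        x = np.array([0.0, 1.0, 2.0, 2.585, 3.322, 4.585])
        k = np.array([1.0, 2.0, 5.0, 9.0, 11.0, 12.0])
        n = np.full(6, 12.0)
        fit = vm.fit_psychometric(x, k, n)
        grid_best = min(
            vm.neg_log_likelihood((a, b, g, l, 0.0), x, k, n)
            for a in np.linspace(0.3, 4.5, 12)
            for b in np.geomspace(0.5, 12, 10)
            for g in np.linspace(0.0, 0.25, 5)
            for l in np.linspace(0.0, 0.25, 5)
        )
        assert fit.nll <= grid_best + 1e-9

    def test_fit_is_deterministic(self, design, control_params):
        trials = vm.simulate_listener(control_params, design, seed=11)
        data = vm.aggregate(trials, "P000")
        a = vm.fit_psychometric(data.x, data.k, data.n)
        b = vm.fit_psychometric(data.x, data.k, data.n)
        assert a == b

    def test_degenerate_ceiling_data_flagged_as_boundary(self):
        x = np.log2(np.arange(1, 25, dtype=float))
        n = np.full(24, 12.0)
        fit = vm.fit_psychometric(x, n.copy(), n)
        assert fit.boundary

    def test_rejects_too_few_levels(self):
        with pytest.raises(ValueError, match="4 levels"):
            vm.fit_psychometric([0, 1, 2], [1, 5, 10], [12, 12, 12])

    def test_fitted_curve_is_monotone_regardless_of_data_noise(self):
        rng = np.random.default_rng(0)
        x = np.log2(np.arange(1, 25, dtype=float))
        n = np.full(24, 12.0)
        k = rng.integers(0, 13, size=24).astype(float)  # pure noise data
        fit = vm.fit_psychometric(x, k, n)
        grid = np.linspace(0, 5, 100)
        p = vm.predict_pcorrect(grid, fit.alpha, fit.beta, fit.gamma, fit.lam)
        assert np.all(np.diff(p) >= -1e-12)


class TestEstimator:
    def test_fit_predict_surface(self, design, control_params):
        trials = vm.simulate_listener(control_params, design, seed=2)
        data = vm.aggregate(trials, "P000")
        est = vm.WeibullPsychometric().fit(data.channels, data.k, data.n)
        assert est.threshold_defined_
        assert 1.0 <= est.threshold_ < 24.0
        assert est.slope_ > 0
        p = est.predict([1, 4, 24])
        assert np.all(np.diff(p) >= 0)

    def test_get_set_params_roundtrip(self):
        est = vm.WeibullPsychometric(n_starts=5)
        assert est.get_params()["n_starts"] == 5
        est.set_params(n_starts=2)
        assert est.get_params()["n_starts"] == 2
        with pytest.raises(ValueError):
            est.set_params(bad=1)


class TestRecoveryAtStudyDesign:
    def test_median_threshold_recovery_within_10pct(self, design):
        """12 digits/level: median recovered threshold near the true value."""
        params = vm.ListenerParams(m=3.14, s=1.08, gamma=0.04, lam=0.0, eta=0.0)
        root = np.random.SeedSequence(202)
        thresholds = []
        for seq in root.spawn(40):
            rng = np.random.default_rng(seq)
            trials = vm.simulate_listener(params, design, rng)
            d = vm.aggregate(trials, "P000")
            thresholds.append(vm.fit_psychometric(d.x, d.k, d.n).threshold)
        assert abs(np.median(thresholds) - 3.14) < 0.1 * 3.14
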