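"""Fokker-Planck closed forms against the discrete master-equation oracle."""

import numpy as np
import pytest

from synapcap import theory
from synapcap.metrics import INFO_SLOPE0
from synapcap.rules import (
    make_hard_rule,
    make_imbalanced_hard_rule,
    make_polynomial_rule,
    make_soft_rule,
)


class TestDriftDiffusion:
    def test_balanced_hard_zero_drift_constant_diffusion(self):
        dd = theory.drift_diffusion(make_hard_rule(0.05, 0.05), 0.5)
        w = np.linspace(0.1, 0.9, 5)
        np.testing.assert_allclose(dd.A(w), 0.0, atol=1e-15)
        np.testing.assert_allclose(dd.B(w), 0.05**2)

    def test_soft_drift_zero_at_equilibrium(self):
        dd = theory.drift_diffusion(make_soft_rule(0.005, 0.01), 0.5)
        np.testing.assert_allclose(dd.A(np.array(0.5)), 0.0, atol=1e-18)
        assert dd.A(np.array(0.3)) > 0 > dd.A(np.array(0.7))

    def test_imbalanced_constant_drift(self):
        a, beta = 0.02, 0.3
        dd = theory.drift_diffusion(make_imbalanced_hard_rule(a, beta), 0.5)
        np.testing.assert_allclose(dd.A(np.linspace(0.2, 0.8, 4)), a * beta)


class TestSoftTheory:
    def test_stationary_moments(self):
        th = theory.soft_theory(0.005, 0.01, 1000)
        assert th["w_bar"] == pytest.approx(0.5)
        assert th["sigma2"] == pytest.approx(0.0025)

    def test_area_invariance(self):
        for c_d in (0.005, 0.02, 0.1):
            th = theory.soft_theory(0.5 * c_d, c_d, 1000)
            assert th["S0"] * th["tau_snr"] == pytest.approx(1000)

    def test_capacity_is_info_slope(self):
        assert theory.soft_info_capacity() == INFO_SLOPE0


class TestHardTheory:
    def test_initial_perturbation_sums_to_a(self):
        # sum over odd k of 8/(pi^2 k^2) = 1; truncation tail ~ 4/(pi^2 K)
        a = 0.01
        assert theory.hard_mean_decay(a, 0.0, n_modes=199) == pytest.approx(a, abs=3e-3 * a)
        assert theory.hard_mean_decay(a, 0.0, n_modes=19_999) == pytest.approx(a, abs=1e-4 * a)

    def test_slowest_mode_rate(self):
        a, t = 0.01, 50_000.0
        # late decay dominated by k=1: rate a^2 pi^2 / 2
        d1 = theory.hard_mean_decay(a, t)
        d2 = theory.hard_mean_decay(a, t + 1000.0)
        rate = np.log(d1 / d2) / 1000.0
        assert rate == pytest.approx(a**2 * np.pi**2 / 2, rel=1e-6)

    def test_double_sum_value(self):
        assert theory.hard_double_sum(199) == pytest.approx(0.5279, abs=5e-4)

    def test_single_mode_underestimates_by_under_6_percent(self):
        assert 1 - theory.hard_double_sum(1) / theory.hard_double_sum(199) < 0.06

    def test_capacity_value(self):
        assert theory.hard_info_capacity() == pytest.approx(0.0968, abs=5e-4)

    def test_improvement_about_18_percent(self):
        assert theory.capacity_improvement() == pytest.approx(18.6, abs=0.2)


class TestLifetimes:
    def test_soft_optimum_closed_form(self):
        res = theory.optimal_soft_lifetime(1000, 30.0)
        assert res["c_d_opt"] == pytest.approx(np.e * 30 / 1000, rel=1e-12)
        assert res["lifetime"] == pytest.approx(1000 / (np.e * 30), rel=1e-12)

    def test_soft_optimum_matches_numeric_scan(self):
        n, theta = 1000, 30.0
        grid = np.geomspace(0.01, 0.5, 4000)
        lives = np.log(n * grid / theta) / grid
        c_best = grid[np.argmax(lives)]
        assert c_best == pytest.approx(np.e * theta / n, rel=2e-3)

    def test_lifetime_linear_in_n(self):
        l1 = theory.optimal_soft_lifetime(1000, 30.0)["lifetime"]
        l2 = theory.optimal_soft_lifetime(2000, 30.0)["lifetime"]
        assert l2 == pytest.approx(2 * l1)

    def test_below_threshold_gives_zero(self):
        assert theory.optimal_soft_lifetime(50, 30.0)["lifetime"] == 0.0

    def test_hard_lowest_order(self):
        res = theory.optimal_hard_lifetime(1000, 30.0)
        assert res["lifetime"] == pytest.approx(768 * 1000 / (np.e * np.pi**6 * 30), rel=1e-12)

    def test_hard_deficit_about_20_percent(self):
        l_soft = theory.optimal_soft_lifetime(1000, 30.0)["lifetime"]
        l_hard = theory.optimal_hard_lifetime(1000, 30.0)["lifetime"]
        assert 100 * (1 - l_hard / l_soft) == pytest.approx(20.1, abs=0.1)

    def test_full_series_beats_lowest_order(self):
        res = theory.optimal_hard_lifetime(1000, 30.0, series=True)
        assert res["lifetime_series"] >= res["lifetime"]


class TestLureVariance:
    def test_zero_mean_inputs_kill_second_term(self):
        t1, t2, t3 = theory.lure_variance_terms(0.0, 1.0, 0.5, 0.01, 100)
        assert t2 == 0.0 and t3 == pytest.approx(25.0)

    def test_zero_mean_weights_kill_third_term(self):
        _, _, t3 = theory.lure_variance_terms(0.5, 0.25, 0.0, 0.01, 100)
        assert t3 == 0.0

    def test_sum_matches_monte_carlo(self, rng):
        n = 1000
        w = rng.normal(0.5, 0.05, n)
        trials = rng.choice([-1.0, 1.0], size=(20_000, n))
        var_mc = (trials @ w).var()
        total = sum(theory.lure_variance_terms(0.0, 1.0, w.mean(), w.var(), n))
        assert var_mc == pytest.approx(total, rel=0.05)


class TestImbalanced:
    def test_beta_zero_reduces_to_balanced(self):
        th = theory.imbalanced_theory(0.05, 0.0, 100, n_max=10)
        eig = th["eigensystem"]
        d = 0.05**2 / 2
        np.testing.assert_allclose(
            eig.eigenvalues, d * np.pi**2 * np.arange(1, 11) ** 2, rtol=1e-12
        )
        assert np.ptp(eig.stationary) < 1e-12  # uniform
        assert th["w_bar"] == pytest.approx(0.5)

    def test_lambda1_increases_with_imbalance(self):
        lam = [
            theory.imbalanced_theory(0.05, b, 100, n_max=2)["eigensystem"].eigenvalues[0]
            for b in (0.0, 0.1, 0.3)
        ]
        assert lam[0] < lam[1] < lam[2]

    def test_info_symmetric_in_beta(self):
        a = theory.imbalanced_theory(0.05, 0.08, 100)["info_per_synapse"]
        b = theory.imbalanced_theory(0.05, -0.08, 100)["info_per_synapse"]
        assert a == pytest.approx(b, rel=1e-4)

    def test_info_maximal_when_balanced(self):
        vals = [
            theory.imbalanced_theory(0.05, b, 100)["info_per_synapse"]
            for b in (0.0, 0.03, 0.1, 0.3)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_matches_master_equation_within_10_percent(self):
        from synapcap.optimize import capacity_discrete

        a, n = 0.05, 100
        for beta in (0.02, 0.05):
            th = theory.imbalanced_theory(a, beta, n)["info_per_synapse"]
            cd = capacity_discrete(make_imbalanced_hard_rule(a, beta), bins=400, n_synapses=n)
            assert th == pytest.approx(cd, rel=0.10)


class TestMasterEquation:
    def test_zero_magnitude_rule_preserves_delta(self):
        rule = make_polynomial_rule((0, 0, 0), (0, 0, 0), 0.0, 1.0)
        init = np.zeros(100)
        init[37] = 1.0
        _, traj = theory.master_evolve(rule, 0.5, 100, 5, init)
        np.testing.assert_array_equal(traj[-1], traj[0])

    def test_probability_conserved(self):
        rule = make_soft_rule(0.01, 0.02)
        init = np.full(200, 1.0 / 200)
        _, traj = theory.master_evolve(rule, 0.5, 200, 200, init)
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-12)

    def test_solved_stationary_is_fixed_point(self):
        # bin width incommensurate with the update so the chain mixes freely
        _, _, _, t_all = theory.build_transition(make_hard_rule(0.02, 0.02), 0.5, 333)
        p = theory.stationary_distribution(t_all)
        assert np.abs(t_all @ p - p).max() < 1e-12
        # coarse-grained bulk density is uniform (the exact jump process keeps
        # period-a ripples that average out over one update length)
        win = 7  # ~ one update width in bins
        smooth = np.convolve(p, np.ones(win) / win, mode="valid")
        assert np.allclose(smooth[33:-33] * 333, 1.0, rtol=0.05)

    def test_soft_stationary_mean_within_bin_resolution(self):
        rule = make_soft_rule(0.005, 0.01)
        centers, _, _, t_all = theory.build_transition(rule, 0.5, 500)
        p = theory.stationary_distribution(t_all)
        h = centers[1] - centers[0]
        assert abs(centers @ p - 0.5) < h

    def test_hard_mean_decay_matches_series_within_1_percent(self):
        """Master-equation mean relaxation vs the mirror-charge series,
        error normalized to the initial perturbation size."""
        a, bins = 0.01, 333  # bin width incommensurate with the update
        rule = make_hard_rule(a, a)
        centers, t_pot, _, t_all = theory.build_transition(rule, 0.5, bins)
        p_inf = theory.stationary_distribution(t_all)
        mu0 = centers @ p_inf
        cur = t_pot @ p_inf
        ts = np.arange(0, int(5 / (a**2 * np.pi**2)) + 1, 25)
        dmu = np.empty(len(ts))
        step = 0
        for i, t in enumerate(ts):
            while step < t:
                cur = t_all @ cur
                step += 1
            dmu[i] = centers @ cur - mu0
        series = theory.hard_mean_decay(a, ts)
        assert np.abs(dmu - series).max() / series[0] < 0.01


class TestTransport:
    def test_zero_displacement_zero_deviation(self):
        rule = make_polynomial_rule((0, 0, 0), (0, 0, 0), 0.0, 1.0)
        res = theory.transport_check(rule, times=[0, 10], bins=100)
        assert res["perturbation"] == 0.0
        np.testing.assert_allclose(res["deviation"], 0.0, atol=1e-14)

    def test_soft_rule_preserves_shape(self):
        """After a potentiation event the soft-rule distribution is rigidly
        transported back: shape deviation stays < 5% of the perturbation."""
        rule = make_soft_rule(0.005, 0.01)
        res = theory.transport_check(rule, times=[0, 50, 100, 200], bins=600)
        assert np.all(res["ratio"] < 0.05)

    def test_hard_rule_distorts_shape(self):
        rule = make_hard_rule(0.01, 0.01)
        res = theory.transport_check(rule, times=[0], bins=250)
        assert res["ratio"][0] > 0.3
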