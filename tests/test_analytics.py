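"""Closed-form theory, clustering index, rate deviations, readout."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from codep.analytics import (RateModelParams, clustering_index,
                             fit_rate_model, grid_sweep,
                             het_vanish_threshold, pairwise_dw_E,
                             pairwise_dw_I, recurrent_max_E, response_norm,
                             smoothed_rate_deviation, steady_state_total_E,
                             train_readout)
from codep.plasticity import ESPParams, ISPParams


class TestSteadyStateTotalE:
    def test_degenerate_case_equals_rheobase(self):
        """No potentiation and no inhibition: the current sits at E*."""
        esp = ESPParams(A_LTP=0.0, A_het=1e-4)
        rm = RateModelParams(nu_star=10.0, E_star=42.0, mean_nu_I=0.0)
        assert steady_state_total_E(esp, rm) == pytest.approx(42.0)

    def test_monotone_decreasing_in_heterosynaptic_rate(self):
        rm = RateModelParams(nu_star=10.0, E_star=20.0)
        values = [steady_state_total_E(ESPParams(A_het=a), rm)
                  for a in np.linspace(1e-6, 1e-3, 100)]
        assert np.all(np.diff(values) < 0)

    def test_monotone_increasing_in_ltp_rate(self):
        rm = RateModelParams(nu_star=10.0, E_star=20.0)
        values = [steady_state_total_E(ESPParams(A_LTP=a), rm)
                  for a in np.linspace(1e-4, 1e-1, 100)]
        assert np.all(np.diff(values) > 0)

    def test_rejects_zero_heterosynaptic_rate(self):
        with pytest.raises(ValueError):
            steady_state_total_E(ESPParams(A_het=0.0), RateModelParams())


class TestHetVanishThreshold:
    def test_first_order_limit(self):
        """nu_I = 0 and tau_ypost*nu* << 1: A_het ~ A_LTP nu* nu tau+ tau_y / E*."""
        esp = ESPParams(A_LTP=1e-2, tau_plus=17.0, tau_ypost=5.0)
        rm = RateModelParams(nu_star=1.0, E_star=10.0, mean_nu_I=0.0,
                             mean_nu_pre=5.0)
        approx = (esp.A_LTP * 1e-3 * 5e-3 * esp.tau_plus * esp.tau_ypost
                  / rm.E_star)
        assert het_vanish_threshold(esp, rm) == pytest.approx(approx, rel=0.01)

    def test_linear_in_ltp_rate(self):
        rm = RateModelParams()
        a1 = het_vanish_threshold(ESPParams(A_LTP=1e-3), rm)
        a2 = het_vanish_threshold(ESPParams(A_LTP=2e-3), rm)
        assert a2 == pytest.approx(2 * a1)

    def test_hand_computed_value(self):
        esp = ESPParams(A_LTP=2e-3, tau_plus=20.0, tau_ypost=100.0)
        rm = RateModelParams(nu_star=8.0, E_star=25.0, mean_nu_I=10.0,
                             mean_w_I=2.0, w_I_star=4.0, mean_nu_pre=12.0)
        # independent hand evaluation of the closed form
        nu_s, nu_pre, nu_i = 8e-3, 12e-3, 10e-3
        denom = 25.0 * (1.0 + 100.0 * (nu_s - nu_i * 2.0 / 4.0))
        expected = 2e-3 * nu_s * nu_pre * 20.0 * 100.0 / denom
        assert het_vanish_threshold(esp, rm) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_invalid_regime_rejected(self):
        esp = ESPParams(tau_ypost=1000.0)
        rm = RateModelParams(nu_star=1.0, mean_nu_I=100.0, mean_w_I=10.0,
                             w_I_star=1.0)
        with pytest.raises(ValueError):
            het_vanish_threshold(esp, rm)


class TestRecurrentMaxE:
    def test_unit_value_at_matched_rates(self):
        esp = ESPParams(A_LTP=1e-3, tau_plus=20.0, A_het=4e-4, tau_ypost=50.0)
        assert recurrent_max_E(esp) == pytest.approx(1.0)

    def test_linear_in_ltp(self):
        esp = ESPParams(A_LTP=1e-3)
        assert recurrent_max_E(esp.with_(A_LTP=2e-3)) == pytest.approx(
            2 * recurrent_max_E(esp))


class TestPairwiseForms:
    def test_pure_ltd_when_no_excitation(self):
        esp = ESPParams()
        dw = pairwise_dw_E(np.inf, np.inf, 10.0, 0.0, 0.5, 2.0, esp)
        gate = np.exp(-(0.5 / esp.I_star) ** esp.gamma)
        assert dw == pytest.approx(
            -esp.A_LTD * np.exp(-10.0 / esp.tau_minus) * 2.0 * gate)

    def test_ltp_het_balance_root(self):
        """E at the balance point makes the bracket vanish (A_LTD = 0)."""
        esp = ESPParams(A_LTD=0.0)
        dt_ltp, dt_het = 8.0, 30.0
        E = (esp.A_LTP / esp.A_het) * np.exp(
            -dt_ltp / esp.tau_plus + dt_het / esp.tau_ypost)
        assert pairwise_dw_E(dt_ltp, dt_het, 0.0, E, 0.3, 1.0, esp
                             ) == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(min_value=1e-3, max_value=10),
           st.floats(min_value=0, max_value=10))
    def test_isp_sign_factorization(self, E, I):
        isp = ISPParams(alpha=1.3)
        dw = pairwise_dw_I(7.0, E, I, isp)
        if abs(E - 1.3 * I) > 1e-9:
            assert np.sign(dw) == np.sign(E - 1.3 * I)

    def test_isp_zero_without_excitation(self):
        assert pairwise_dw_I(7.0, 0.0, 4.0, ISPParams()) == 0.0


class TestClusteringIndex:
    def test_only_coactive_survive(self):
        assert clustering_index([1.0, 2.0], [0.0, 0.0]) == 1.0

    def test_only_independent_survive(self):
        assert clustering_index([0.0], [3.0, 1.0]) == -1.0

    def test_equal_means_give_zero(self):
        assert clustering_index([2.0, 4.0], [3.0, 3.0]) == 0.0

    def test_all_zero_defined_as_zero(self):
        assert clustering_index([0.0], [0.0]) == 0.0

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=1,
                    max_size=8),
           st.lists(st.floats(min_value=0, max_value=10), min_size=1,
                    max_size=8))
    def test_bounded(self, a, b):
        assert -1.0 <= clustering_index(a, b) <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clustering_index([], [1.0])


class TestSmoothedRateDeviation:
    def test_baseline_activity_gives_near_zero_norm(self, rng):
        T, baseline = 2000.0, 20.0
        trials = [[np.sort(rng.uniform(0, T, int(baseline * T / 1000)))
                   for _ in range(3)] for _ in range(200)]
        dev = smoothed_rate_deviation(trials, [baseline] * 3, T)
        # trial-averaged Poisson noise: relative SD ~ 0.11 per bin here
        assert np.abs(dev).max() < 0.5
        assert response_norm(dev) < 0.25 * np.sqrt(dev.size)

    def test_doubled_bin_conserves_mass(self):
        """A single doubled-rate bin keeps its integral under smoothing."""
        T, Delta_T, baseline = 2000.0, 20.0, 50.0
        n_per_bin = baseline * Delta_T / 1000.0  # 1 spike per bin
        times = np.arange(0, T, Delta_T) + 5.0
        times = np.sort(np.append(times, 1005.0))  # one extra spike
        raw = smoothed_rate_deviation([[times]], [baseline], T,
                                      Delta_T=Delta_T, sigma_r=1e-6)
        k = int(1000.0 / Delta_T)
        assert raw[0, k] == pytest.approx(1.0 / n_per_bin)
        smooth = smoothed_rate_deviation([[times]], [baseline], T,
                                         Delta_T=Delta_T, sigma_r=10.0)
        assert smooth[0].sum() == pytest.approx(raw[0].sum(), rel=1e-6)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            smoothed_rate_deviation([[np.array([1.0])]], [0.0], 100.0)


class TestReadout:
    def test_constant_target_zero_variance_rates(self):
        rates = [np.zeros((88, 5))]
        targets = [np.column_stack([np.full(88, 0.3), np.full(88, -0.2)])]
        model = train_readout(rates, targets)
        assert np.allclose(model.a, 0.0) and np.allclose(model.b, 0.0)
        assert model.x0 == pytest.approx(0.3)
        assert model.y0 == pytest.approx(-0.2)

    def test_exact_recovery_of_linear_targets(self, rng):
        n_bins, n_neurons = 88, 12
        rates = [rng.standard_normal((n_bins, n_neurons)) for _ in range(4)]
        a_true = rng.uniform(-0.05, 0.05, n_neurons)
        b_true = rng.uniform(-0.05, 0.05, n_neurons)
        targets = [np.column_stack([r @ a_true + 0.1, r @ b_true - 0.05])
                   for r in rates]
        model = train_readout(rates, targets)
        resid = 0.0
        for r, t in zip(rates, targets):
            x, y = model.predict(r)
            resid += np.sum((x - t[:, 0]) ** 2 + (y - t[:, 1]) ** 2)
        assert resid < 1e-8

    def test_fit_beats_random_readouts(self, rng):
        rates = [rng.standard_normal((88, 6))]
        targets = [np.column_stack([np.tanh(rates[0][:, 0]) * 0.5,
                                    np.tanh(rates[0][:, 1]) * 0.5])]
        model = train_readout(rates, targets)
        x, y = model.predict(rates[0])
        best = np.sum((x - targets[0][:, 0]) ** 2
                      + (y - targets[0][:, 1]) ** 2)
        for _ in range(100):
            a = rng.standard_normal(6) * 0.5
            b = rng.standard_normal(6) * 0.5
            xr = rates[0] @ a
            yr = rates[0] @ b
            r = np.sum((xr - targets[0][:, 0]) ** 2
                       + (yr - targets[0][:, 1]) ** 2)
            assert best <= r + 1e-12

    def test_targets_outside_range_rejected(self):
        with pytest.raises(ValueError):
            train_readout([np.zeros((4, 2))],
                          [np.column_stack([np.ones(4), np.zeros(4)])])


class TestFitRateModel:
    def test_recovers_threshold_linear_relation(self):
        E_star, nu_star = 30.0, 12.0
        X = np.linspace(35, 120, 12)
        nu = nu_star * (X / E_star - 1.0)
        rm = fit_rate_model(X, nu, mean_nu_pre=10.0)
        assert rm.nu_star == pytest.approx(nu_star, rel=1e-9)
        assert rm.E_star == pytest.approx(E_star, rel=1e-9)

    def test_subthreshold_points_ignored(self):
        X = np.array([5.0, 10.0, 40.0, 80.0])
        nu = np.array([0.0, 0.0, 5.0, 25.0])
        rm = fit_rate_model(X, nu, mean_nu_pre=10.0)
        assert rm.E_star == pytest.approx(30.0)


class TestGridSweep:
    def test_cartesian_product_and_values(self):
        df = grid_sweep(lambda a, b: a * b, {"a": [1, 2], "b": [3, 4]})
        assert len(df) == 4
        assert set(df["value"]) == {3, 4, 6, 8}
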