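"""Co-dependent plasticity: kernel, gate, traces, event semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codep.analytics import pairwise_dw_E, pairwise_dw_I
from codep.engine import FeedforwardSimulation, scheduled_drive
from codep.neurons import NeuronParams
from codep.plasticity import (CoTraceState, ESPParams, ISPParams,
                              build_distance_kernel, esp_apply,
                              inhibitory_gate, isp_apply)


class TestDistanceKernel:
    def test_infinite_sigma_is_all_to_all(self, rng):
        k = build_distance_kernel(np.arange(10.0), np.inf)
        e = rng.uniform(0, 1, 10)
        assert np.allclose(k.apply(e), e.sum())

    def test_tiny_sigma_is_scaled_identity(self):
        n = 8
        k = build_distance_kernel(np.arange(float(n)), 1e-3)
        # F[i,i] -> N under the mean-mass normalization
        assert np.allclose(np.diag(k.F), n)
        off = k.F - np.diag(np.diag(k.F))
        assert np.all(np.abs(off) < 1e-10)

    def test_normalization_identity(self, rng):
        """sum_i E_i ~= N * sum_j Etilde_j for equally spaced synapses."""
        n = 100
        k = build_distance_kernel(np.arange(float(n)), 2.0)
        e = rng.uniform(0.5, 1.5, n)
        ratio = k.apply(e).sum() / e.sum()
        assert abs(ratio - n) / n < 0.02

    def test_identity_exact_at_infinite_sigma(self, rng):
        n = 50
        k = build_distance_kernel(np.arange(float(n)), np.inf)
        e = rng.uniform(0, 2, n)
        assert k.apply(e).sum() == pytest.approx(n * e.sum(), rel=1e-12)

    def test_rows_nonnegative(self, rng):
        k = build_distance_kernel(rng.uniform(0, 10, 20), 1.5)
        assert np.all(k.F >= 0)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            build_distance_kernel([0.0, 1.0], 0.0)


class TestInhibitoryGate:
    def test_open_at_zero(self):
        assert inhibitory_gate(0.0, 1.0, 2.0, 10.0) == 1.0

    def test_e_inverse_at_i_star(self):
        assert inhibitory_gate(1.0, 1.0, 2.0, 10.0) == pytest.approx(
            np.exp(-1.0))

    def test_hard_block_above_threshold(self):
        assert inhibitory_gate(10.1, 1.0, 2.0, 10.0) == 0.0

    @given(st.floats(min_value=0, max_value=50),
           st.floats(min_value=0, max_value=50))
    def test_monotone_nonincreasing(self, i1, i2):
        lo, hi = sorted((i1, i2))
        g_lo = inhibitory_gate(lo, 2.0, 2.0, 8.0)
        g_hi = inhibitory_gate(hi, 2.0, 2.0, 8.0)
        assert 0.0 <= g_hi <= g_lo <= 1.0

    def test_default_threshold_is_seamless(self, esp_params):
        """Default I_th sits where the smooth gate reaches 1e-3."""
        assert inhibitory_gate(esp_params.I_th, esp_params.I_star,
                               esp_params.gamma, esp_params.I_th
                               ) == pytest.approx(1e-3, rel=1e-9)


class TestTraces:
    def _traces(self, esp=None, isp=None, n_exc=3, n_inh=2):
        return CoTraceState(n_exc, n_inh, 0.1, esp or ESPParams(),
                            isp or ISPParams())

    def test_filtered_current_decays_without_input(self):
        tr = self._traces()
        tr.e_tilde[:] = 1.0
        tau_E = tr.esp.tau_E
        for k in range(1000):
            tr.update_currents(-70.0, np.zeros(3), 0.0)
        assert np.allclose(tr.e_tilde, np.exp(-100.0 / tau_E), rtol=1e-9)

    def test_no_inhibitory_drive_at_gaba_reversal(self):
        tr = self._traces()
        tr.I = 0.5
        tr.update_currents(-80.0, np.zeros(3), g_gaba_total=5.0)
        # source term vanishes at E_GABA: pure decay
        assert tr.I == pytest.approx(0.5 * np.exp(-0.1 / tr.isp.tau_I))

    def test_filtered_current_converges_to_driving_current(self):
        """Constant NMDA conductance: Etilde -> -g H(u) (u - E_NMDA)."""
        tr = self._traces()
        g = np.array([0.4, 0.0, 0.0])
        u = -55.0
        from codep.neurons import mg_block
        target = -g * mg_block(u) * (u - 0.0)
        for _ in range(200_000):
            tr.update_currents(u, g, 0.0)
        assert np.allclose(tr.e_tilde, target, rtol=1e-6)

    def test_spike_traces_nonnegative_and_decay(self, rng):
        tr = self._traces()
        for _ in range(500):
            tr.decay_spike_traces()
            tr.jump_spike_traces(pre_exc=np.flatnonzero(rng.random(3) < 0.1),
                                 pre_inh=np.flatnonzero(rng.random(2) < 0.1),
                                 post_spiked=rng.random() < 0.05)
            assert np.all(tr.x_plus >= 0) and tr.y_post_E >= 0

    def test_current_traces_nonnegative_in_physiological_range(self, rng):
        tr = self._traces()
        for _ in range(2000):
            u = rng.uniform(-80.0, 0.0)
            tr.update_currents(u, rng.uniform(0, 1, 3), rng.uniform(0, 2))
            assert np.all(tr.e_tilde >= -1e-12) and tr.I >= -1e-12


class TestEventSemantics:
    def test_weights_clipped_to_bounds(self, rng):
        esp = ESPParams(A_LTP=100.0, A_het=0.0, A_LTD=0.0)
        tr = CoTraceState(4, 0, 0.1, esp, ISPParams())
        tr.x_plus[:] = 1.0
        tr.E = np.full(4, 10.0)
        w = np.full(4, 5.0)
        esp_apply(w, tr, post_spiked=True, esp=esp)
        assert np.all(w == esp.w_max)
        esp2 = esp.with_(A_LTP=0.0, A_LTD=1e6)
        tr.y_post_minus = 1.0
        w2 = np.full(4, 5.0)
        esp_apply(w2, tr, pre_exc=np.array([0, 1]), post_spiked=False,
                  esp=esp2)
        assert np.all(w2[:2] == esp2.w_min)
        assert np.all(w2[2:] == 5.0)

    def test_gate_blocks_all_excitatory_changes(self):
        esp = ESPParams()
        tr = CoTraceState(2, 0, 0.1, esp, ISPParams())
        tr.x_plus[:] = 1.0
        tr.y_post_minus = 1.0
        tr.E = np.full(2, 5.0)
        tr.I = esp.I_th * 1.01
        w = np.full(2, 1.0)
        esp_apply(w, tr, pre_exc=np.array([0]), post_spiked=True, esp=esp)
        assert np.all(w == 1.0)

    def test_lone_pre_spike_without_recent_post_is_silent(self):
        esp = ESPParams()
        tr = CoTraceState(1, 0, 0.1, esp, ISPParams())
        tr.E = np.array([5.0])
        w = np.array([1.0])
        esp_apply(w, tr, pre_exc=np.array([0]), post_spiked=False, esp=esp)
        assert w[0] == 1.0  # y_post_minus is zero

    def test_isp_zero_at_balance_setpoint(self):
        isp = ISPParams(alpha=1.2)
        tr = CoTraceState(1, 2, 0.1, ESPParams(), isp)
        tr.e_tilde[:] = 3.0
        tr.I = 3.0 / 1.2
        tr.x_isp[:] = 1.0
        tr.y_post = 1.0
        w = np.array([1.0, 2.0])
        isp_apply(w, tr, pre_inh=np.array([0]), post_spiked=True, isp=isp)
        assert np.allclose(w, [1.0, 2.0])

    def test_isp_zero_without_excitation(self):
        isp = ISPParams()
        tr = CoTraceState(1, 1, 0.1, ESPParams(), isp)
        tr.I = 4.0
        tr.x_isp[:] = 1.0
        tr.y_post = 1.0
        w = np.array([1.0])
        isp_apply(w, tr, pre_inh=np.array([0]), post_spiked=True, isp=isp)
        assert w[0] == 1.0

    def test_isp_sign_follows_balance(self):
        isp = ISPParams(alpha=1.0)
        for E, I, sign in ((5.0, 2.0, +1), (2.0, 5.0, -1)):
            tr = CoTraceState(1, 1, 0.1, ESPParams(), isp)
            tr.e_tilde[:] = E
            tr.I = I
            tr.y_post = 1.0
            w = np.array([10.0])
            isp_apply(w, tr, pre_inh=np.array([0]), isp=isp)
            assert np.sign(w[0] - 10.0) == sign


class TestPairwiseClosedForm:
    """Event-driven rule on isolated spike pairs vs the closed forms."""

    def _run_pair(self, lag_ms, E, I, w0, esp, extra_post=None):
        """Simulate a single pre/post pair with frozen current traces."""
        dt = 0.1
        neuron = NeuronParams(u_th=1e6)  # no intrinsic spikes
        pre_t, post_t = 50.0, 50.0 + lag_ms
        posts = [post_t] if extra_post is None else [extra_post, post_t]
        sim = FeedforwardSimulation(
            neuron, w_exc=[w0], w_inh=[],
            exc_drive=scheduled_drive([np.array([pre_t])], dt),
            esp=esp, scheduled_post=np.array(posts), dt=dt)
        sim.traces.update_currents = lambda *a, **k: None
        sim.traces.E = np.array([E])
        sim.traces.I = I
        sim.run(200.0)
        return sim.w_exc[0] - w0

    @pytest.mark.parametrize("lag", [5.0, 10.0, 25.0])
    @pytest.mark.parametrize("E,I", [(5.0, 0.0), (2.0, 0.5), (8.0, 1.0)])
    def test_ltp_pair_matches_closed_form(self, lag, E, I):
        esp = ESPParams(A_LTD=0.0, A_het=0.0)
        dw = self._run_pair(lag, E, I, 1.0, esp)
        expected = pairwise_dw_E(lag, np.inf, np.inf, E, I, 1.0, esp)
        assert dw == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("lag", [5.0, 15.0])
    def test_ltd_pair_matches_closed_form(self, lag):
        """Post-before-pre: depression proportional to the weight."""
        esp = ESPParams(A_LTP=0.0, A_het=0.0)
        E, I, w0 = 4.0, 0.2, 2.0
        dw = self._run_pair(-lag, E, I, w0, esp)
        expected = pairwise_dw_E(np.inf, np.inf, lag, E, I, w0, esp)
        assert dw == pytest.approx(expected, abs=1e-10)

    def test_full_triplet_matches_closed_form(self):
        """Post, then pre->post: LTP + heterosynaptic + LTD combined."""
        esp = ESPParams()
        E, I, w0 = 3.0, 0.4, 1.5
        dt_ltp, dt_het = 10.0, 40.0
        # post at 20, pre at 50 (LTD lag 30), post at 60 (LTP lag 10)
        dw = self._run_pair(dt_ltp, E, I, w0, esp, extra_post=20.0)
        gate = np.exp(-(I / esp.I_star) ** esp.gamma)
        exp_ltp = esp.A_LTP * np.exp(-dt_ltp / esp.tau_plus) * E
        exp_het = esp.A_het * np.exp(-dt_het / esp.tau_ypost) * E ** 2
        w_after_ltd = w0 - gate * esp.A_LTD * np.exp(-30.0 / esp.tau_minus) * w0
        expected = w_after_ltd + gate * (exp_ltp - exp_het) - w0
        assert dw == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("lag", [-15.0, -5.0, 5.0, 15.0])
    def test_isp_pair_matches_closed_form(self, lag):
        dt = 0.1
        isp = ISPParams()
        E, I, w0 = 4.0, 2.0, 3.0
        neuron = NeuronParams(u_th=1e6)
        pre_t = 100.0
        post_t = pre_t + lag
        sim = FeedforwardSimulation(
            neuron, w_exc=[], w_inh=[w0],
            inh_drive=scheduled_drive([np.array([pre_t])], dt),
            isp=isp, scheduled_post=np.array([post_t]), dt=dt)
        # freeze the current traces: compartment-wide E and the I trace
        sim.traces.update_currents = lambda *a, **k: None
        sim.traces.e_tilde = np.array([E])
        sim.traces.I = I
        sim.run(200.0)
        expected = pairwise_dw_I(lag, E, I, isp)
        assert sim.w_inh[0] - w0 == pytest.approx(expected, abs=1e-10)

    def test_isp_symmetric_in_lag(self):
        isp = ISPParams()
        assert pairwise_dw_I(12.0, 3.0, 1.0, isp) == pytest.approx(
            pairwise_dw_I(-12.0, 3.0, 1.0, isp))

    def test_gate_kills_change_at_high_inhibition(self):
        esp = ESPParams()
        assert pairwise_dw_E(10.0, 20.0, 30.0, 5.0, 1e9, 1.0, esp) == 0.0


class TestSignStructure:
    """STDP sign structure at low pairing frequency (weak inhibition)."""

    def test_pre_before_post_potentiates(self):
        esp = ESPParams()
        dw = pairwise_dw_E(10.0, np.inf, np.inf, 5.0, 0.1, 1.0, esp)
        assert dw > 0

    def test_post_before_pre_depresses(self):
        esp = ESPParams()
        dw = pairwise_dw_E(np.inf, np.inf, 10.0, 5.0, 0.1, 1.0, esp)
        assert dw < 0

    def test_event_driven_sign_structure(self):
        """Simulated isolated pairs show the LTP/LTD sign asymmetry."""
        esp = ESPParams()
        t = TestPairwiseClosedForm()
        assert t._run_pair(+10.0, 5.0, 0.1, 1.0, esp) > 0
        assert t._run_pair(-10.0, 5.0, 0.1, 1.0, esp) < 0
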