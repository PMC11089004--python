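"""Neuron models: Mg block, refractoriness, equilibria, compartment coupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codep.engine import FeedforwardSimulation, bernoulli_drive
from codep.neurons import (DendriticNeuronParams, NeuronParams, PointNeuron,
                           TwoLayerNeuron, adaptive_refractory,
                           coupling_from_distance, mg_block)


class TestMgBlock:
    @pytest.mark.parametrize(
        "u, a, expected",
        [
            (0.0, 0.28, 1.0 / 1.28),     # at the NMDA reversal the exponent is 0
            (-55.0, 0.0, 1.0),           # no magnesium -> no block
            (-70.0, 0.28, 0.0444877240505226),  # hand evaluation of closed form
        ],
    )
    def test_values(self, u, a, expected):
        assert mg_block(u, a_NMDA=a, b_NMDA=-0.062, E_NMDA=0.0) == pytest.approx(
            expected, rel=1e-12)

    @given(st.floats(min_value=-90, max_value=0))
    def test_in_unit_interval(self, u):
        h = mg_block(u)
        assert 0.0 < h <= 1.0

    def test_monotone_increasing_for_negative_slope(self):
        us = np.linspace(-90, 0, 200)
        h = mg_block(us, b_NMDA=-0.062)
        assert np.all(np.diff(h) > 0)

    def test_negative_a_rejected(self):
        with pytest.raises(ValueError):
            mg_block(-70.0, a_NMDA=-0.1)


class TestAdaptiveRefractory:
    def test_zero_when_reset_threshold_at_reversal(self, adaptive_params):
        p = adaptive_params.with_(u_th_star=0.0)  # == E_NMDA
        assert adaptive_refractory(p) == pytest.approx(0.0)

    def test_equals_tau_th_at_e_fold(self, adaptive_params):
        # u_th_star - u_th_0 = e * (E_NMDA - u_th_0)
        p = adaptive_params.with_(u_th_0=-50.0,
                                  u_th_star=-50.0 + np.e * 50.0)
        assert adaptive_refractory(p) == pytest.approx(p.tau_th)

    def test_matches_threshold_decay_simulation(self, adaptive_params):
        """First time the decaying threshold reaches E_NMDA."""
        p = adaptive_params
        dt = 1e-3
        u_th = p.u_th_star
        t = 0.0
        while u_th > p.E_NMDA:
            u_th = p.u_th_0 + (u_th - p.u_th_0) * np.exp(-dt / p.tau_th)
            t += dt
        assert t == pytest.approx(adaptive_refractory(p), abs=2 * dt)

    def test_invalid_parameters_rejected(self, adaptive_params):
        with pytest.raises(ValueError):
            adaptive_refractory(adaptive_params.with_(u_th_star=-10.0))


class TestCouplingFromDistance:
    def test_reference_distance(self):
        J, a = coupling_from_distance(50.0, 50.0)
        assert J == pytest.approx(1.0)
        assert a == pytest.approx(0.5)

    def test_far_limit(self):
        J, a = coupling_from_distance(1e9, 50.0)
        assert J == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_half_distance(self):
        J, a = coupling_from_distance(25.0, 50.0)
        assert J == pytest.approx(4.0)
        assert a == pytest.approx(0.8)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            coupling_from_distance(0.0, 50.0)


class TestPointNeuron:
    def test_rest_is_equilibrium(self, neuron_params):
        n = PointNeuron(neuron_params, dt=0.1)
        for _ in range(1000):
            n.step()
        assert n.u == pytest.approx(neuron_params.u_rest)

    def test_constant_current_steady_state(self, neuron_params):
        n = PointNeuron(neuron_params.with_(u_th=1e6), dt=0.1)
        for _ in range(50_000):
            n.step(I_ext=0.05)
        assert n.u == pytest.approx(
            neuron_params.u_rest + neuron_params.R * 0.05, rel=1e-4)

    def test_ampa_clamp_steady_state(self, neuron_params):
        """Algebraic equilibrium u = (u_rest + g E_AMPA) / (1 + g)."""
        p = neuron_params.with_(u_th=1e6)
        n = PointNeuron(p, n_exc=1, dt=0.1)
        g = 0.5
        comp = np.exp(0.1 / p.tau_AMPA)  # cancel the in-step decay
        for _ in range(20_000):
            n.g_ampa = g * comp    # hold conductance at g during integration
            n.step()
            n.g_nmda[:] = 0.0
        expected = (p.u_rest + g * p.E_AMPA) / (1.0 + g)
        assert n.u == pytest.approx(expected, rel=1e-4)

    def test_euler_matches_exponential_closed_form(self, neuron_params):
        """Free relaxation tracks the exact exponential to <1e-3 rel error."""
        dt = 0.1
        n = PointNeuron(neuron_params, dt=dt)
        n.u = -55.0
        u0 = n.u
        for k in range(1, 2001):
            n.step()
            exact = neuron_params.u_rest + (u0 - neuron_params.u_rest) * np.exp(
                -k * dt / neuron_params.tau_m)
            denom = abs(u0 - neuron_params.u_rest)
            assert abs(n.u - exact) / denom < 1e-3

    def test_fixed_refractory_separates_spikes(self, neuron_params, rng):
        p = neuron_params.with_(tau_ref=5.0)
        dt = 0.1
        n = PointNeuron(p, n_exc=20, dt=dt)
        spikes = []
        for k in range(100_000):
            jumps = (rng.random(20) < 0.01) * 0.8
            if n.step(exc_jumps=jumps):
                spikes.append(k * dt)
        isi = np.diff(spikes)
        assert len(spikes) > 20
        assert isi.min() >= p.tau_ref - 1e-9

    def test_adaptive_refractory_bound(self, adaptive_params, rng):
        dt = 0.1
        n = PointNeuron(adaptive_params, n_exc=20, dt=dt)
        spikes = []
        for k in range(100_000):
            jumps = (rng.random(20) < 0.02) * 1.5
            if n.step(exc_jumps=jumps):
                spikes.append(k * dt)
        assert len(spikes) > 20
        isi_min = np.diff(spikes).min()
        assert isi_min >= adaptive_refractory(adaptive_params) - dt

    def test_voltage_stays_in_physiological_range(self, neuron_params, rng):
        """Without external current u is confined to [E_GABA, E_NMDA]."""
        p = neuron_params
        n = PointNeuron(p, n_exc=50, n_inh=20, dt=0.1)
        lo = min(p.E_GABA, p.u_reset)
        for _ in range(100_000):
            e = (rng.random(50) < 0.02) * rng.uniform(0, 2)
            i = float((rng.random(20) < 0.02).sum()) * 3.0
            n.step(exc_jumps=e, inh_jump=i)
            assert lo - 1e-9 <= n.u <= p.E_NMDA + 1e-9

    def test_conductance_decay_between_events(self, neuron_params):
        n = PointNeuron(neuron_params, n_exc=1, dt=0.1)
        n.step(exc_jumps=np.array([1.0]))
        g_prev = n.g_nmda[0]
        for _ in range(100):
            n.step()
            assert 0.0 < n.g_nmda[0] < g_prev
            g_prev = n.g_nmda[0]

    def test_rejects_bad_dt(self, neuron_params):
        with pytest.raises(ValueError):
            PointNeuron(neuron_params, dt=0.0)

    def test_rejects_nonfinite_state(self, neuron_params):
        n = PointNeuron(neuron_params, dt=0.1)
        n.u = np.nan
        with pytest.raises(FloatingPointError):
            n.step()


class TestNeuronParamsValidation:
    def test_time_constants_positive(self):
        with pytest.raises(ValueError):
            NeuronParams(tau_m=-1.0)

    def test_reset_below_threshold(self):
        with pytest.raises(ValueError):
            NeuronParams(u_reset=-40.0, u_th=-50.0)

    def test_adaptive_needs_u_th_star_above_reversal(self):
        with pytest.raises(ValueError):
            NeuronParams(threshold_mode="adaptive", u_th_star=-10.0)


class TestTwoLayerNeuron:
    def _params(self, J):
        return DendriticNeuronParams(neuron=NeuronParams(),
                                     J=np.asarray(J, dtype=float))

    def test_stationary_at_rest(self):
        n = TwoLayerNeuron(self._params([1.0, 1.0]), [2, 2], [1, 1], dt=0.1)
        for _ in range(1000):
            n.step()
        assert n.u_soma == pytest.approx(-70.0)
        assert np.allclose(n.u, -70.0)

    def test_zero_coupling_decouples(self):
        n = TwoLayerNeuron(self._params([0.0]), [1], [0], dt=0.1)
        n.u[0] = -50.0
        u_soma_before = n.u_soma
        n.step()
        assert n.u_soma == u_soma_before  # no current flows

    def test_branch_attenuation_matches_coupling_law(self):
        """Soma clamped at ubar: branch settles at u_rest + a*(ubar-u_rest)."""
        J = 2.0
        a = J / (1.0 + J)
        n = TwoLayerNeuron(self._params([J]), [1], [0], dt=0.1)
        ubar = -50.0
        for _ in range(20_000):
            n.step(clamp_soma=ubar)
        expected = -70.0 + a * (ubar + 70.0)
        assert n.u[0] == pytest.approx(expected, rel=1e-4)

    def test_branch_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TwoLayerNeuron(self._params([1.0, 1.0]), [1], [1], dt=0.1)

    def test_branches_do_not_spike(self):
        """Strong branch input produces an NMDA plateau, not a reset."""
        n = TwoLayerNeuron(self._params([0.5, 0.5]), [5, 5], [0, 0], dt=0.1)
        for _ in range(2000):
            n.step(exc_jumps_per_branch=[np.full(5, 0.2), None])
        # branch potential can exceed the somatic threshold
        assert n.u[0] > n.p.neuron.u_th
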