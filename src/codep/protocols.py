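"""Turn-key single-neuron plasticity experiments.

Each runner reproduces a classic induction protocol with the
co-dependent rules: voltage-, frequency- and distance-dependent STDP
pairings, a feedforward current-stability sweep over the interaction
length sigma, receptive-field formation/reshaping under learning
windows, and dendritic clustering of co-active synapses.  Runners are
pure functions of (parameters, seed); the printed protocol constants
(pair counts, lags, intervals) are the defaults and can be scaled down
for quick runs.

Weight changes are reported as percent change of the probed weight from
its initial value; raw weights are also returned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analytics
from .engine import (DendriticSimulation, FeedforwardSimulation,
                     bernoulli_drive, scheduled_drive, silent_drive)
from .neurons import DendriticNeuronParams, NeuronParams
from .plasticity import ESPParams, ISPParams, build_distance_kernel
from .stimuli import BernoulliSpiker, OUPathways, PathwaySpec

__all__ = [
    "ProtocolResult",
    "prob_from_rate",
    "run_voltage_stdp",
    "run_frequency_stdp",
    "run_distance_stdp",
    "run_feedforward_stability",
    "run_receptive_field",
    "run_dendritic_clustering",
]


@dataclass
class ProtocolResult:
    """Tidy result table plus provenance (config hash, seed)."""

    table: pd.DataFrame
    config: dict
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prob_from_rate(rate_hz: float, dt: float = 0.1,
                   tau_ref: float = 5.0) -> float:
    """Invert the refractory-Bernoulli rate formula: p from nu (Hz)."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0:
        return 0.0
    n = int(round(tau_ref / dt))
    q = rate_hz * dt / 1000.0
    p = q
    for _ in range(8):  # fixed-point iteration, converges for p << 1
        p = q / (1.0 - p) ** n
    return float(p)


def _pulse_current(times: np.ndarray, amp_nA: float, dur_ms: float,
                   T: float, dt: float):
    """I_ext(t) callable: rectangular pulses at the given start times."""
    n_steps = int(round(T / dt)) + 1
    on = np.zeros(n_steps, dtype=bool)
    n_dur = max(int(round(dur_ms / dt)), 1)
    for t in times:
        k = int(round(t / dt))
        on[k:k + n_dur] = True
    return lambda t: amp_nA if on[int(round(t / dt))] else 0.0


def _default_point_params() -> NeuronParams:
    return NeuronParams()


# ----------------------------------------------------------------------
def run_voltage_stdp(depol_levels: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4),
                     initial_weight: float = 1.0,
                     repetitions: int = 15, interval_ms: float = 10_000.0,
                     n_pairs: int = 5, pair_rate_hz: float = 50.0,
                     lag_ms: float = 10.0,
                     esp: Optional[ESPParams] = None,
                     neuron: Optional[NeuronParams] = None,
                     dt: float = 0.1, seed: int = 0) -> ProtocolResult:
    """Pre-before-post pairing under graded postsynaptic depolarization.

    Bursts of ``n_pairs`` presynaptic and postsynaptic spikes at
    ``pair_rate_hz`` with a +``lag_ms`` pre-before-post offset, repeated
    ``repetitions`` times ``interval_ms`` apart.  Postsynaptic spike
    times enter the plasticity rule directly (they do not touch the
    membrane); depolarization is varied through a constant current clamp
    whose amplitude is ``depol_levels`` (nA).  Returns percent weight
    change against the mean depolarization over the 200-ms window from
    the first presynaptic spike of each burst.
    """
    esp = esp or ESPParams()
    neuron = (neuron or _default_point_params()).with_(u_th=1e6)
    # intrinsic spiking disabled: postsynaptic events are supplied to the
    # plasticity rule directly, as in the experimental emulation
    isi = 1000.0 / pair_rate_hz
    rows = []
    for amp in depol_levels:
        pre, post = [], []
        for r in range(repetitions):
            t0 = 100.0 + r * interval_ms
            for k in range(n_pairs):
                pre.append(t0 + k * isi)
                post.append(t0 + k * isi + lag_ms)
        T = pre[-1] + 500.0
        sim = FeedforwardSimulation(
            neuron, w_exc=[initial_weight], w_inh=[],
            exc_drive=scheduled_drive([np.asarray(pre)], dt),
            esp=esp, scheduled_post=np.asarray(post),
            I_ext=(lambda t, a=amp: a), dt=dt, seed=seed)
        # record membrane potential in the 200-ms windows
        depol_samples = []
        t_cursor = 0.0
        for r in range(repetitions):
            t0 = 100.0 + r * interval_ms
            sim.run(t0 - t_cursor)
            out = sim.run(200.0, record_every=dt)
            depol_samples.append(out["u"].mean())
            t_cursor = t0 + 200.0
        sim.run(T - t_cursor)
        w_final = sim.w_exc[0]
        rows.append({
            "clamp_nA": amp,
            "mean_depolarization_mV": float(np.mean(depol_samples)),
            "w_final": w_final,
            "dw_percent": 100.0 * (w_final - initial_weight) / initial_weight,
        })
    cfg = dict(initial_weight=initial_weight, repetitions=repetitions,
               interval_ms=interval_ms, n_pairs=n_pairs,
               pair_rate_hz=pair_rate_hz, lag_ms=lag_ms)
    return ProtocolResult(pd.DataFrame(rows), cfg, seed)


# ----------------------------------------------------------------------
def run_frequency_stdp(freqs_hz: Sequence[float], lag_ms: float = 10.0,
                       neighbor_rate_hz: float = 0.0,
                       n_pairs: int = 60, initial_weight: float = 1.0,
                       neighbor_w_exc: float = 2.0, neighbor_w_inh: float = 4.0,
                       n_trials: int = 1,
                       esp: Optional[ESPParams] = None,
                       neuron: Optional[NeuronParams] = None,
                       pulse_nA: float = 3.0, pulse_ms: float = 2.0,
                       dt: float = 0.1, seed: int = 0) -> ProtocolResult:
    """STDP pairing frequency sweep, optionally with active neighbors.

    ``n_pairs`` pre/post pairs at each frequency; postsynaptic spikes are
    elicited by 3-nA, 2-ms current pulses.  ``lag_ms`` may be positive
    (pre-before-post) or negative.  With ``neighbor_rate_hz`` > 0 a
    static excitatory+inhibitory synapse pair fires at that rate and the
    weight change is averaged over ``n_trials`` trials.
    """
    esp = esp or ESPParams()
    neuron = neuron or _default_point_params()
    rows = []
    for f in freqs_hz:
        if f > 1000.0 / (2.0 * abs(lag_ms)):
            raise ValueError(
                f"pairing frequency {f} Hz incompatible with lag {lag_ms} ms")
        period = 1000.0 / f
        dws = []
        for trial in range(max(n_trials, 1)):
            t0 = 50.0 + abs(lag_ms)
            pre = np.array([t0 + k * period for k in range(n_pairs)])
            pulses = pre + lag_ms - pulse_ms  # spike fires ~pulse end
            T = pre[-1] + period + 100.0
            w_exc = [initial_weight]
            drives = [pre]
            if neighbor_rate_hz > 0:
                w_exc.append(neighbor_w_exc)
                rng = np.random.default_rng(seed * 1000 + trial + 1)
                p_n = prob_from_rate(neighbor_rate_hz, dt, 5.0)
                nbr = BernoulliSpiker(1, 5.0, dt, rng)
                inh = BernoulliSpiker(1, 2.5, dt, rng)
                p_i = prob_from_rate(neighbor_rate_hz, dt, 2.5)
                base = scheduled_drive([pre], dt)

                def exc_drive(k, base=base, nbr=nbr, p_n=p_n):
                    probe = base(k)
                    n_idx = nbr.step(p_n)
                    if n_idx.size:
                        return np.concatenate([probe, n_idx + 1])
                    return probe

                inh_drive = (lambda k, inh=inh, p_i=p_i: inh.step(p_i))
                w_inh = [neighbor_w_inh]
            else:
                exc_drive = scheduled_drive([pre], dt)
                inh_drive = None
                w_inh = []
            sim = FeedforwardSimulation(
                neuron, w_exc=w_exc, w_inh=w_inh,
                exc_drive=exc_drive, inh_drive=inh_drive,
                esp=esp, I_ext=_pulse_current(pulses, pulse_nA, pulse_ms,
                                              T, dt),
                exc_plastic_mask=[True] + [False] * (len(w_exc) - 1),
                dt=dt, seed=seed)
            sim.run(T)
            dws.append(100.0 * (sim.w_exc[0] - initial_weight)
                       / initial_weight)
        rows.append({"freq_hz": f, "lag_ms": lag_ms,
                     "neighbor_rate_hz": neighbor_rate_hz,
                     "dw_percent": float(np.mean(dws)),
                     "dw_sd": float(np.std(dws))})
    cfg = dict(lag_ms=lag_ms, n_pairs=n_pairs,
               neighbor_rate_hz=neighbor_rate_hz, n_trials=n_trials)
    return ProtocolResult(pd.DataFrame(rows), cfg, seed)


# ----------------------------------------------------------------------
def run_distance_stdp(mode: str = "curve",
                      lags_ms: Sequence[float] = (-40, -20, -5, 5, 20, 35, 60),
                      intervals_s: Sequence[float] = (30, 90, 180),
                      distances_um: Sequence[float] = (1.0, 3.0, 6.0, 10.0),
                      n_events: int = 60, event_interval_ms: float = 500.0,
                      burst_isi_ms: float = 20.0, dx_um: float = 3.0,
                      sigma_um: float = 3.16,
                      interval_fixed_s: float = 90.0,
                      initial_weight: float = 1.0,
                      esp: Optional[ESPParams] = None,
                      neuron: Optional[NeuronParams] = None,
                      pulse_nA: float = 3.0, pulse_ms: float = 2.0,
                      dt: float = 0.1, seed: int = 0) -> ProtocolResult:
    """Burst pairing with two synapses at a defined electrotonic distance.

    ``mode='curve'``: weight change of a single probed synapse versus the
    lag between its presynaptic spike and the first spike of a
    three-spike postsynaptic burst (the companion synapse is silent).
    ``mode='interval'``: strong LTP induction (lag 5 ms) at one synapse
    followed after a varying interval by weak induction (lag 35 ms) at a
    neighbor ``dx_um`` away.  ``mode='distance'``: same with the interval
    fixed at ``interval_fixed_s`` and distance varied.
    """
    esp = (esp or ESPParams()).with_(sigma=sigma_um)
    neuron = neuron or _default_point_params()

    def induction_times(t0, lag):
        pre = np.array([t0 + k * event_interval_ms for k in range(n_events)])
        bursts = np.concatenate([pre + lag + j * burst_isi_ms
                                 for j in range(3)])
        return pre, np.sort(bursts)

    def run_two_synapse(dx, schedule):
        """schedule: list of (synapse_index, t_start, lag)."""
        kernel = build_distance_kernel([0.0, dx], sigma_um)
        pre_times = [[], []]
        pulse_times = []
        T = 0.0
        for idx, t0, lag in schedule:
            pre, bursts = induction_times(t0, lag)
            pre_times[idx].extend(pre)
            pulse_times.extend(bursts - pulse_ms)
            T = max(T, bursts[-1])
        T += 500.0
        sim = FeedforwardSimulation(
            neuron, w_exc=[initial_weight, initial_weight], w_inh=[],
            exc_drive=scheduled_drive(
                [np.asarray(sorted(pre_times[0])),
                 np.asarray(sorted(pre_times[1]))], dt),
            esp=esp, kernel=kernel,
            I_ext=_pulse_current(np.asarray(sorted(pulse_times)), pulse_nA,
                                 pulse_ms, T, dt),
            dt=dt, seed=seed)
        sim.run(T)
        return sim.w_exc

    rows = []
    induction_len = n_events * event_interval_ms
    if mode == "curve":
        for lag in lags_ms:
            w = run_two_synapse(1e6, [(0, 200.0 + abs(min(lag, 0)), lag)])
            rows.append({"lag_ms": lag, "dw_percent":
                         100.0 * (w[0] - initial_weight) / initial_weight})
    elif mode == "interval":
        for gap_s in intervals_s:
            t_weak = 200.0 + induction_len + gap_s * 1000.0
            w = run_two_synapse(dx_um, [(0, 200.0, 5.0), (1, t_weak, 35.0)])
            rows.append({"interval_s": gap_s, "dw_percent":
                         100.0 * (w[1] - initial_weight) / initial_weight})
    elif mode == "distance":
        for dx in distances_um:
            t_weak = 200.0 + induction_len + interval_fixed_s * 1000.0
            w = run_two_synapse(dx, [(0, 200.0, 5.0), (1, t_weak, 35.0)])
            rows.append({"distance_um": dx, "dw_percent":
                         100.0 * (w[1] - initial_weight) / initial_weight})
    else:
        raise ValueError("mode must be curve|interval|distance")
    cfg = dict(mode=mode, n_events=n_events, sigma_um=sigma_um,
               event_interval_ms=event_interval_ms)
    return ProtocolResult(pd.DataFrame(rows), cfg, seed)


# ----------------------------------------------------------------------
def run_feedforward_stability(sigma: float = 2.0,
                              n_exc: int = 800, n_inh: int = 200,
                              rate_profile: str = "uniform",
                              rate_max_hz: float = 18.0,
                              inh_rate_hz: float = 18.0,
                              w_exc_init: float = 0.05, w_inh: float = 0.3,
                              enforced_post_rate: float = 1.0,
                              esp: Optional[ESPParams] = None,
                              neuron: Optional[NeuronParams] = None,
                              gate_off: bool = True,
                              T_max: float = 200_000.0,
                              check_every: float = 20_000.0,
                              equil_tol: float = 0.01,
                              dt: float = 0.1, seed: int = 0
                              ) -> ProtocolResult:
    """Plastic excitatory afferents with spatial interactions of width sigma.

    ``n_exc`` plastic excitatory synapses at unit spacing and ``n_inh``
    static inhibitory synapses; presynaptic rates are either uniformly
    distributed in (0, rate_max_hz] per synapse or constant at
    rate_max_hz/2.  Enforced postsynaptic plasticity events at 1 Hz keep
    the rule active when output spiking is weak.  The run ends when the
    windowed mean of the summed filtered NMDA current changes by less
    than ``equil_tol`` per window (or at ``T_max``), and reports the
    per-synapse current statistics and the survival mask.
    """
    esp = esp or ESPParams(A_LTP=1e-3, A_het=1e-5, A_LTD=2e-4,
                           tau_E=200.0, tau_ypost=200.0)
    if gate_off:
        esp = esp.with_(I_star=1e12, I_th=None)
    neuron = neuron or _default_point_params()
    rng = np.random.default_rng(seed)
    if rate_profile == "uniform":
        rates = rng.uniform(0.0, rate_max_hz, n_exc)
        rates = np.maximum(rates, 1e-3)
    elif rate_profile == "constant":
        rates = np.full(n_exc, rate_max_hz / 2.0)
    else:
        raise ValueError("rate_profile must be uniform|constant")
    p_exc = np.array([prob_from_rate(r, dt, 5.0) for r in rates])
    p_inh = prob_from_rate(inh_rate_hz, dt, 2.5)
    kernel = build_distance_kernel(np.arange(n_exc, dtype=float), sigma)
    sim = FeedforwardSimulation(
        neuron,
        w_exc=np.full(n_exc, w_exc_init), w_inh=np.full(n_inh, w_inh),
        exc_drive=bernoulli_drive(n_exc, p_exc, 5.0, dt,
                                  np.random.default_rng(seed + 1)),
        inh_drive=bernoulli_drive(n_inh, p_inh, 2.5, dt,
                                  np.random.default_rng(seed + 2)),
        esp=esp, kernel=kernel, enforced_post_rate=enforced_post_rate,
        dt=dt, seed=seed + 3)
    prev = None
    converged = False
    t_ran = 0.0
    while t_ran < T_max:
        out = sim.run(check_every, average_from=check_every / 2.0)
        t_ran += check_every
        cur = out["mean_E_total"]
        if prev is not None and prev > 0 and abs(cur - prev) / prev < equil_tol:
            converged = True
            break
        prev = cur
    # average per-synapse currents over a final measurement window
    n_meas = int(round(5_000.0 / dt))
    acc = np.zeros(n_exc)
    for _ in range(n_meas):
        sim.run(dt)
        acc += sim.traces.e_tilde
    e_syn = acc / n_meas
    survival = sim.w_exc > 10.0 * esp.w_min
    table = pd.DataFrame({
        "synapse": np.arange(n_exc), "rate_hz": rates,
        "e_tilde": e_syn, "weight": sim.w_exc, "survived": survival})
    cfg = dict(sigma=sigma, n_exc=n_exc, n_inh=n_inh,
               rate_profile=rate_profile, T_max=T_max)
    extras = {"mean_current": float(e_syn.mean()),
              "sd_current": float(e_syn.std()),
              "total_E": float(e_syn.sum()),
              "survival_fraction": float(survival.mean()),
              "converged": converged, "post_rate_hz": sim.rate_hz}
    return ProtocolResult(table, cfg, seed, extras)


# ----------------------------------------------------------------------
def run_receptive_field(seed: int = 0,
                        n_exc_per_pathway: int = 100,
                        n_inh_per_pathway: int = 25,
                        w_exc_init: float = 0.08, w_inh_init: float = 2.5,
                        settle_ms: float = 2_000.0,
                        consolidate_ms: float = 10_000.0,
                        final_ms: float = 5_000.0,
                        esp: Optional[ESPParams] = None,
                        isp: Optional[ISPParams] = None,
                        neuron: Optional[NeuronParams] = None,
                        pathway: Optional[PathwaySpec] = None,
                        window1_alpha=None, window2_alpha=None,
                        dt: float = 0.1) -> ProtocolResult:
    """Receptive-field formation and reshaping across two learning windows.

    Eight OU-correlated pathways feed a single neuron with plastic
    excitatory and (more slowly) plastic inhibitory synapses.  During
    each 700-ms learning window inhibition is clamped to background
    (disinhibition) and the excitatory pathways fire at
    alpha_mu * p_active in the final 200 ms; window 1 peaks at pathway 6
    and window 2 at pathway 4.  Returns mean weights per pathway at
    snapshots before/after each window.
    """
    from .stimuli import (WINDOW1_ALPHA, WINDOW2_ALPHA, LearningWindowSpec,
                          apply_learning_window)

    # baseline inhibition must keep the gate hard-blocked between windows
    # (I* well below the baseline I trace) for the acquired profile to
    # survive ongoing activity
    esp = esp or ESPParams(A_LTP=6e-4, A_het=6e-7, A_LTD=1e-4, I_star=60.0,
                           tau_E=200.0)
    isp = isp or ISPParams(A_ISP=2e-5, alpha=1.0)
    neuron = neuron or _default_point_params()
    spec = pathway or PathwaySpec(n_exc_per_pathway=n_exc_per_pathway,
                                  n_inh_per_pathway=n_inh_per_pathway,
                                  seed=seed, dt=dt)
    w1 = LearningWindowSpec(settle_ms, window1_alpha or WINDOW1_ALPHA)
    w2 = LearningWindowSpec(w1.t_end + consolidate_ms,
                            window2_alpha or WINDOW2_ALPHA)
    T = w2.t_end + final_ms
    windows = (w1, w2)
    rng = np.random.default_rng(seed)
    ou = OUPathways(spec, rng)
    n_exc = spec.n_pathways * spec.n_exc_per_pathway
    n_inh = spec.n_pathways * spec.n_inh_per_pathway
    exc_spiker = BernoulliSpiker(n_exc, spec.tau_ref_exc, dt, rng)
    inh_spiker = BernoulliSpiker(n_inh, spec.tau_ref_inh, dt, rng)

    state = {"k": -1, "inh_idx": None}

    def exc_drive(k):
        state["k"] = k
        t = k * dt
        ou.step()
        pe, pi = ou.probabilities()
        pe, pi = apply_learning_window(pe, pi, t, spec, windows)
        state["inh_idx"] = inh_spiker.step(pi)
        return exc_spiker.step(pe)

    def inh_drive(k):
        return state["inh_idx"]

    sim = FeedforwardSimulation(
        neuron, w_exc=np.full(n_exc, w_exc_init),
        w_inh=np.full(n_inh, w_inh_init),
        exc_drive=exc_drive, inh_drive=inh_drive,
        esp=esp, isp=isp, dt=dt, seed=seed + 7)

    def pathway_means():
        we = sim.w_exc.reshape(spec.n_pathways, spec.n_exc_per_pathway)
        wi = sim.w_inh.reshape(spec.n_pathways, spec.n_inh_per_pathway)
        return we.mean(axis=1), wi.mean(axis=1)

    snaps = {}
    sim.run(w1.t_start)
    snaps["before_w1"] = pathway_means()
    sim.run(w1.duration)
    snaps["after_w1"] = pathway_means()
    sim.run(w2.t_start - w1.t_end)
    snaps["before_w2"] = pathway_means()
    sim.run(w2.duration)
    snaps["after_w2"] = pathway_means()
    sim.run(T - w2.t_end)
    snaps["final"] = pathway_means()
    rows = []
    for label, (we, wi) in snaps.items():
        for mu in range(spec.n_pathways):
            rows.append({"snapshot": label, "pathway": mu + 1,
                         "mean_w_exc": we[mu], "mean_w_inh": wi[mu]})
    cfg = dict(n_exc_per_pathway=spec.n_exc_per_pathway,
               n_inh_per_pathway=spec.n_inh_per_pathway,
               consolidate_ms=consolidate_ms)
    return ProtocolResult(pd.DataFrame(rows), cfg, seed,
                          extras={"snapshots": snaps})


# ----------------------------------------------------------------------
def run_dendritic_clustering(coactive_count: int = 16,
                             coupling_J: float = 1.0,
                             matching: str = "independent",
                             n_exc: int = 32, n_inh: int = 16,
                             w_exc_init: float = 1.0, w_inh_init: float = 2.0,
                             T: float = 30_000.0,
                             esp: Optional[ESPParams] = None,
                             isp: Optional[ISPParams] = None,
                             neuron: Optional[NeuronParams] = None,
                             tau_OU: float = 50.0, p_star: float = 0.025,
                             p_bg_exc: float = 2e-4, p_bg_inh: float = 4e-4,
                             plastic: bool = True,
                             dt: float = 0.1, seed: int = 0
                             ) -> ProtocolResult:
    """Clustering of co-active synapses on a plastic dendritic branch.

    A two-layer neuron with two equally coupled branches: branch 0 hosts
    ``n_exc`` excitatory and ``n_inh`` inhibitory plastic synapses,
    branch 1 identical static synapses as a noise source.  The first
    ``coactive_count`` excitatory afferents share one OU rate signal;
    the rest are independent.  With ``matching='matching'`` half of the
    inhibitory afferents follow the co-active signal.  Returns the
    clustering index of the final excitatory weights.
    """
    if not 1 <= coactive_count <= n_exc:
        raise ValueError("coactive_count must be in [1, n_exc]")
    if matching not in ("independent", "matching"):
        raise ValueError("matching must be independent|matching")
    esp = esp or ESPParams(A_LTP=0.05, A_het=2e-3, A_LTD=0.01, I_star=2.0,
                           tau_E=200.0)
    isp = isp or ISPParams(A_ISP=5e-5, alpha=1.0)
    base = neuron or _default_point_params()
    params = DendriticNeuronParams(neuron=base,
                                   J=np.array([coupling_J, coupling_J]))
    rng = np.random.default_rng(seed)
    # OU signals: 1 shared + independent ones for remaining E, all I, noise
    n_ind_exc = n_exc - coactive_count
    n_match_inh = n_inh // 2 if matching == "matching" else 0
    n_ou = 1 + n_ind_exc + (n_inh - n_match_inh) + n_exc + n_inh
    spec = PathwaySpec(n_pathways=n_ou, n_exc_per_pathway=1,
                       n_inh_per_pathway=0, p_bg_exc=p_bg_exc,
                       p_bg_inh=p_bg_inh, p_star=p_star, tau_OU=tau_OU,
                       dt=dt, seed=seed)
    ou = OUPathways(spec, rng)
    exc_spiker = BernoulliSpiker(n_exc, 5.0, dt, rng)
    inh_spiker = BernoulliSpiker(n_inh, 2.5, dt, rng)
    exc_n_spiker = BernoulliSpiker(n_exc, 5.0, dt, rng)
    inh_n_spiker = BernoulliSpiker(n_inh, 2.5, dt, rng)

    # index map into the OU vector
    i0 = 1
    idx_ind_exc = np.arange(i0, i0 + n_ind_exc)
    i0 += n_ind_exc
    idx_ind_inh = np.arange(i0, i0 + n_inh - n_match_inh)
    i0 += n_inh - n_match_inh
    idx_noise_exc = np.arange(i0, i0 + n_exc)
    i0 += n_exc
    idx_noise_inh = np.arange(i0, i0 + n_inh)

    state = {}

    def exc_drive(k):
        ou.step()
        y = np.maximum(ou.y, 0.0) * p_star
        pe = np.empty(n_exc)
        pe[:coactive_count] = y[0]
        pe[coactive_count:] = y[idx_ind_exc]
        pe += p_bg_exc
        pi = np.empty(n_inh)
        if n_match_inh:
            pi[:n_match_inh] = y[0]
            pi[n_match_inh:] = y[idx_ind_inh]
        else:
            pi[:] = y[idx_ind_inh]
        pi += p_bg_inh
        state["inh"] = inh_spiker.step(pi)
        state["exc_n"] = exc_n_spiker.step(y[idx_noise_exc] + p_bg_exc)
        state["inh_n"] = inh_n_spiker.step(y[idx_noise_inh] + p_bg_inh)
        return exc_spiker.step(pe)

    sim = DendriticSimulation(
        params,
        w_exc=np.full(n_exc, w_exc_init), w_inh=np.full(n_inh, w_inh_init),
        w_exc_noise=np.full(n_exc, w_exc_init),
        w_inh_noise=np.full(n_inh, w_inh_init),
        exc_drive=exc_drive, inh_drive=lambda k: state["inh"],
        exc_noise_drive=lambda k: state["exc_n"],
        inh_noise_drive=lambda k: state["inh_n"],
        esp=esp if plastic else None, isp=isp if plastic else None,
        dt=dt, seed=seed + 11)
    sim.run(T)
    w = sim.w_exc
    index = analytics.clustering_index(w[:coactive_count], w[coactive_count:])
    table = pd.DataFrame({
        "synapse": np.arange(n_exc),
        "coactive": np.arange(n_exc) < coactive_count,
        "weight": w})
    cfg = dict(coactive_count=coactive_count, coupling_J=coupling_J,
               matching=matching, n_exc=n_exc, n_inh=n_inh, T=T)
    return ProtocolResult(table, cfg, seed,
                          extras={"clustering_index": index,
                                  "w_inh": sim.w_inh.copy()})
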