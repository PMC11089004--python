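"""Single-postsynaptic-neuron simulation loops.

:class:`FeedforwardSimulation` couples one point neuron with plastic
excitatory and inhibitory afferents; :class:`DendriticSimulation` does
the same for a two-layer neuron with one plastic and one static noise
branch.  Both follow the per-step schedule

1. decay conductances, AHP, adaptive threshold and spike traces
2. apply presynaptic conductance jumps
3. forward-Euler membrane update, threshold test, reset
4. plasticity updates (reading pre-jump spike traces and the current
   traces from the end of the previous step)
5. spike-trace increments and current-trace relaxation

Inputs are supplied as *drives*: callables mapping the step index to the
indices of presynaptic sources spiking in that step.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from .neurons import DendriticNeuronParams, NeuronParams, PointNeuron, TwoLayerNeuron
from .plasticity import (CoTraceState, DistanceKernel, ESPParams, ISPParams,
                         esp_apply, isp_apply)
from .stimuli import BernoulliSpiker

__all__ = [
    "bernoulli_drive",
    "scheduled_drive",
    "silent_drive",
    "FeedforwardSimulation",
    "DendriticSimulation",
]

_EMPTY = np.empty(0, dtype=np.int64)


def bernoulli_drive(n: int, p, tau_ref: float, dt: float,
                    rng: np.random.Generator) -> Callable[[int], np.ndarray]:
    """Refractory Bernoulli drive; ``p`` scalar, array, or callable(t)->p."""
    spiker = BernoulliSpiker(n, tau_ref, dt, rng)
    if callable(p):
        return lambda k: spiker.step(p(k * dt))
    return lambda k: spiker.step(p)


def scheduled_drive(spike_times: Sequence[np.ndarray], dt: float
                    ) -> Callable[[int], np.ndarray]:
    """Drive from per-source spike-time arrays (ms), binned to steps."""
    events: dict[int, list[int]] = {}
    for src, times in enumerate(spike_times):
        for t in np.asarray(times, dtype=float):
            events.setdefault(int(round(t / dt)), []).append(src)
    table = {k: np.asarray(v, dtype=np.int64) for k, v in events.items()}
    return lambda k: table.get(k, _EMPTY)


def silent_drive(k: int) -> np.ndarray:
    return _EMPTY


class FeedforwardSimulation:
    """One conductance-based point neuron with plastic afferents.

    Plasticity is active only for the rules whose parameter objects are
    supplied; passing ``esp=None`` freezes the excitatory weights.  The
    optional ``enforced_post_rate`` adds Poisson postsynaptic events to
    the plasticity rule only (they do not touch the membrane), and
    ``scheduled_post`` injects postsynaptic plasticity events at given
    times, as used by the pairing protocols.
    """

    def __init__(self, neuron_params: NeuronParams, w_exc, w_inh,
                 exc_drive=None, inh_drive=None,
                 esp: Optional[ESPParams] = None,
                 isp: Optional[ISPParams] = None,
                 kernel: Optional[DistanceKernel] = None,
                 dt: float = 0.1,
                 enforced_post_rate: float = 0.0,
                 scheduled_post: Optional[np.ndarray] = None,
                 I_ext=None,
                 exc_plastic_mask=None,
                 seed: int = 0):
        self.w_exc = np.asarray(w_exc, dtype=float).copy()
        self.w_inh = np.asarray(w_inh, dtype=float).copy()
        self.dt = dt
        self.np_ = neuron_params
        self.neuron = PointNeuron(neuron_params, self.w_exc.size,
                                  self.w_inh.size, dt)
        self.esp = esp
        self.isp = isp
        trace_esp = esp if esp is not None else ESPParams()
        trace_isp = isp if isp is not None else ISPParams()
        self.traces = CoTraceState(self.w_exc.size, self.w_inh.size, dt,
                                   trace_esp, trace_isp, kernel=kernel)
        self.exc_drive = exc_drive or silent_drive
        self.inh_drive = inh_drive or silent_drive
        self.rng = np.random.default_rng(seed)
        self._p_enforced = enforced_post_rate * 1e-3 * dt  # Hz -> per step
        self._sched_post = set()
        if scheduled_post is not None:
            self._sched_post = {int(round(t / dt))
                                for t in np.asarray(scheduled_post)}
        self.I_ext = I_ext  # callable(t_ms) -> nA, or None
        self.exc_plastic_mask = (np.asarray(exc_plastic_mask, dtype=bool)
                                 if exc_plastic_mask is not None else None)
        self.t = 0.0
        self._k = 0
        self.post_spike_times: list[float] = []

    def run(self, T: float, record_every: Optional[float] = None,
            average_from: Optional[float] = None) -> dict:
        """Simulate ``T`` ms; return recordings.

        ``record_every`` stores weight/trace snapshots at that cadence;
        ``average_from`` accumulates time averages of the current traces
        (E_total, I, E/I ratio) from that time (ms, relative to the start
        of this call) to the end.
        """
        n_steps = int(round(T / self.dt))
        p = self.np_
        esp_on = self.esp is not None
        isp_on = self.isp is not None
        rec = {"t": [], "w_exc": [], "w_inh": [], "E_total": [], "I": [],
               "u": []}
        rec_stride = (int(round(record_every / self.dt))
                      if record_every else None)
        avg_start = (self._k + int(round(average_from / self.dt))
                     if average_from is not None else None)
        acc_E = acc_I = 0.0
        acc_n = 0
        tr = self.traces
        neuron = self.neuron
        for _ in range(n_steps):
            k = self._k
            exc_idx = self.exc_drive(k)
            inh_idx = self.inh_drive(k)
            exc_jumps = None
            if exc_idx.size:
                exc_jumps = np.zeros(self.w_exc.size)
                exc_jumps[exc_idx] = self.w_exc[exc_idx]
            inh_jump = float(self.w_inh[inh_idx].sum()) if inh_idx.size else 0.0
            I_ext = self.I_ext(self.t) if self.I_ext is not None else 0.0
            spiked = neuron.step(exc_jumps, inh_jump, I_ext)
            if spiked:
                self.post_spike_times.append(self.t)
            tr.decay_spike_traces()
            post_plast = spiked
            if self._p_enforced and self.rng.random() < self._p_enforced:
                post_plast = True
            if k in self._sched_post:
                post_plast = True
            if esp_on:
                if self.exc_plastic_mask is not None:
                    frozen = self.w_exc[~self.exc_plastic_mask]
                    esp_apply(self.w_exc, tr, exc_idx, post_plast, self.esp)
                    self.w_exc[~self.exc_plastic_mask] = frozen
                else:
                    esp_apply(self.w_exc, tr, exc_idx, post_plast, self.esp)
            if isp_on:
                isp_apply(self.w_inh, tr, inh_idx, post_plast, self.isp)
            tr.jump_spike_traces(exc_idx, inh_idx, post_plast)
            tr.update_currents(neuron.u, neuron.g_nmda, neuron.g_gaba,
                               a_NMDA=p.a_NMDA, b_NMDA=p.b_NMDA,
                               E_NMDA=p.E_NMDA, E_GABA=p.E_GABA)
            if avg_start is not None and k >= avg_start:
                acc_E += tr.E_total
                acc_I += tr.I
                acc_n += 1
            if rec_stride and k % rec_stride == 0:
                rec["t"].append(self.t)
                rec["w_exc"].append(self.w_exc.copy())
                rec["w_inh"].append(self.w_inh.copy())
                rec["E_total"].append(tr.E_total)
                rec["I"].append(tr.I)
                rec["u"].append(neuron.u)
            self._k += 1
            self.t = self._k * self.dt
        out = {k_: (np.asarray(v) if v else np.empty(0)) for k_, v in rec.items()}
        out["post_spikes"] = np.asarray(self.post_spike_times)
        if acc_n:
            out["mean_E_total"] = acc_E / acc_n
            out["mean_I"] = acc_I / acc_n
            out["EI_ratio"] = (acc_E / acc_I) if acc_I > 0 else np.inf
        return out

    @property
    def rate_hz(self) -> float:
        """Mean postsynaptic rate over the whole simulated span (Hz)."""
        if self.t == 0:
            return 0.0
        return 1000.0 * len(self.post_spike_times) / self.t


class DendriticSimulation:
    """Two-layer neuron with one plastic branch and one noise branch.

    Branch 0 hosts the plastic excitatory and inhibitory synapses; its
    plasticity traces are driven by the branch membrane potential and
    branch-local currents.  Branch 1 receives static background input.
    """

    def __init__(self, params: DendriticNeuronParams,
                 w_exc, w_inh, w_exc_noise, w_inh_noise,
                 exc_drive, inh_drive, exc_noise_drive, inh_noise_drive,
                 esp: Optional[ESPParams] = None,
                 isp: Optional[ISPParams] = None,
                 kernel: Optional[DistanceKernel] = None,
                 dt: float = 0.1, seed: int = 0):
        if params.n_branches != 2:
            raise ValueError("expected two branches (plastic + noise)")
        self.p = params
        self.dt = dt
        self.w_exc = np.asarray(w_exc, dtype=float).copy()
        self.w_inh = np.asarray(w_inh, dtype=float).copy()
        self.w_exc_noise = np.asarray(w_exc_noise, dtype=float)
        self.w_inh_noise = np.asarray(w_inh_noise, dtype=float)
        self.neuron = TwoLayerNeuron(
            params,
            [self.w_exc.size, self.w_exc_noise.size],
            [self.w_inh.size, self.w_inh_noise.size], dt)
        self.esp = esp
        self.isp = isp
        self.traces = CoTraceState(self.w_exc.size, self.w_inh.size, dt,
                                   esp if esp else ESPParams(),
                                   isp if isp else ISPParams(), kernel=kernel)
        self.drives = (exc_drive, inh_drive, exc_noise_drive, inh_noise_drive)
        self.rng = np.random.default_rng(seed)
        self.t = 0.0
        self._k = 0
        self.post_spike_times: list[float] = []

    def run(self, T: float) -> dict:
        n_steps = int(round(T / self.dt))
        p = self.p.neuron
        exc_d, inh_d, exc_nd, inh_nd = self.drives
        tr = self.traces
        neuron = self.neuron
        esp_on = self.esp is not None
        isp_on = self.isp is not None
        for _ in range(n_steps):
            k = self._k
            exc_idx = exc_d(k)
            inh_idx = inh_d(k)
            exc_n_idx = exc_nd(k)
            inh_n_idx = inh_nd(k)
            jumps0 = None
            if exc_idx.size:
                jumps0 = np.zeros(self.w_exc.size)
                jumps0[exc_idx] = self.w_exc[exc_idx]
            jumps1 = None
            if exc_n_idx.size:
                jumps1 = np.zeros(self.w_exc_noise.size)
                jumps1[exc_n_idx] = self.w_exc_noise[exc_n_idx]
            inh0 = float(self.w_inh[inh_idx].sum()) if inh_idx.size else 0.0
            inh1 = (float(self.w_inh_noise[inh_n_idx].sum())
                    if inh_n_idx.size else 0.0)
            spiked = neuron.step([jumps0, jumps1], [inh0, inh1])
            if spiked:
                self.post_spike_times.append(self.t)
            tr.decay_spike_traces()
            if esp_on:
                esp_apply(self.w_exc, tr, exc_idx, spiked, self.esp)
            if isp_on:
                isp_apply(self.w_inh, tr, inh_idx, spiked, self.isp)
            tr.jump_spike_traces(exc_idx, inh_idx, spiked)
            u_branch = float(neuron.u[0])
            tr.update_currents(u_branch, neuron.g_nmda[0],
                               float(neuron.g_gaba[0]),
                               a_NMDA=p.a_NMDA, b_NMDA=p.b_NMDA,
                               E_NMDA=p.E_NMDA, E_GABA=p.E_GABA)
            self._k += 1
            self.t = self._k * self.dt
        return {"w_exc": self.w_exc.copy(), "w_inh": self.w_inh.copy(),
                "post_spikes": np.asarray(self.post_spike_times)}
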