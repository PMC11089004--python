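"""Recurrent spiking network with plastic E->E and I->E synapses.

The network holds N_E excitatory and N_I inhibitory adaptive-threshold
conductance-based LIF neurons with sparse random block connectivity.
Excitatory-to-excitatory and inhibitory-to-excitatory synapses are
plastic (co-dependent ESP / ISP); the other two blocks are static.
Each excitatory neuron carries its own current traces: the E trace sums
the filtered NMDA currents of its recurrent excitatory synapses (the
compartment-wide neighborhood) and the I trace filters its total GABA_A
current.

A learning phase with a decaying external drive lets the plasticity
rules shape the connectivity toward the excitatory-current setpoint and
EI balance; a recall phase (plasticity frozen) probes the resulting
self-sustained dynamics with structured stimulation patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .neurons import NeuronParams, mg_block
from .plasticity import ESPParams, ISPParams, inhibitory_gate

__all__ = ["RecurrentNetConfig", "RecurrentNetwork", "build_network",
           "compute_impact"]


def _default_neuron() -> NeuronParams:
    # slow threshold decay (long effective refractory) and a strong AHP
    # bound single-neuron burst rates; without them synchronized network
    # events destabilize the learned weights
    return NeuronParams(threshold_mode="adaptive", u_reset=-60.0,
                        u_th_0=-50.0, u_th_star=20.0, tau_th=20.0,
                        A_AHP=0.5, tau_AHP=100.0)


@dataclass
class RecurrentNetConfig:
    """Topology, weights and plasticity settings of the recurrent network.

    The full-scale study conditions use 1000 E / 250 I neurons and hours
    of learning; :meth:`desk_scale` returns a 200 E / 50 I configuration
    with faster learning rates suited to minutes of simulated time.
    Connection probabilities and initial weights are package choices
    exposed here; the acceptance gate for the learned network is
    self-sustained activity, not specific weight values.
    """

    n_exc: int = 1000
    n_inh: int = 250
    p_EE: float = 0.2
    p_EI: float = 0.2
    p_IE: float = 0.2
    p_II: float = 0.2
    # initial/static weights scale inversely with the recurrent in-degree;
    # these defaults suit the full-scale (1000 E) population
    w_EE_init: float = 0.12
    w_EI: float = 0.2
    w_IE_init: float = 0.8
    w_II: float = 0.06
    w_ext: float = 2.0
    neuron: NeuronParams = field(default_factory=_default_neuron)
    esp: ESPParams = field(default_factory=lambda: ESPParams(
        A_LTP=8e-4, A_het=2.7e-6, A_LTD=4e-5, I_star=150.0,
        tau_E=1000.0, tau_ypost=50.0))
    isp: ISPParams = field(default_factory=lambda: ISPParams(
        A_ISP=2e-5, alpha=1.1))
    # (duration_ms, per-step probability) stages of the learning drive
    drive_schedule: Sequence[tuple] = (
        (300_000.0, 0.01), (300_000.0, 0.001), (35_400_000.0, 0.0001))
    tau_ref_ext: float = 5.0
    # plasticity is enabled only after the network settles into its
    # ongoing state; the startup burst would otherwise be interpreted as
    # an enormous excitatory current and crush the weights
    plasticity_warmup_ms: float = 10_000.0
    dt: float = 0.1
    seed: int = 0
    silence_limit_ms: float = 10_000.0

    def __post_init__(self) -> None:
        for name in ("p_EE", "p_EI", "p_IE", "p_II"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_EE == 0.0 or self.p_IE == 0.0:
            raise ValueError("plastic blocks (E->E, I->E) cannot be empty")
        if self.neuron.threshold_mode != "adaptive":
            raise ValueError("recurrent network requires adaptive threshold")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "RecurrentNetConfig":
        """Small network + aggressive learning rates for short runs."""
        kwargs = dict(
            n_exc=200, n_inh=50,
            esp=ESPParams(A_LTP=6e-3, A_het=2e-5, A_LTD=2e-4, I_star=150.0,
                          tau_E=1000.0, tau_ypost=50.0),
            isp=ISPParams(A_ISP=5e-5, alpha=1.1),
            w_EE_init=0.4, w_EI=1.0, w_IE_init=2.0, w_II=0.3,
            # constant moderate drive: at this scale the near-zero
            # late-stage drive makes the active state metastable and
            # re-ignition transients destabilize the weights
            drive_schedule=((100_000.0, 0.002),),
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _random_block(rng, n_pre, n_post, p, no_self=False):
    """Sparse random adjacency: (pre, post) index arrays, pre-sorted."""
    mask = rng.random((n_pre, n_post)) < p
    if no_self:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


class _Block:
    """One connectivity block with pre-sorted synapse arrays."""

    def __init__(self, pre, post, w, n_pre):
        self.pre = pre
        self.post = post
        self.w = w
        counts = np.bincount(pre, minlength=n_pre)
        self.indptr = np.concatenate([[0], np.cumsum(counts)])

    def out_slice(self, j: int) -> slice:
        return slice(self.indptr[j], self.indptr[j + 1])

    def dense(self, n_pre: int, n_post: int) -> np.ndarray:
        m = np.zeros((n_post, n_pre))
        m[self.post, self.pre] = self.w
        return m


class RecurrentNetwork:
    """Simulation state of the recurrent E/I network."""

    def __init__(self, config: RecurrentNetConfig):
        c = config
        self.c = c
        rng = np.random.default_rng(c.seed)
        self.rng = rng
        nE, nI = c.n_exc, c.n_inh
        self.nE, self.nI = nE, nI
        preEE, postEE = _random_block(rng, nE, nE, c.p_EE, no_self=True)
        preEI, postEI = _random_block(rng, nE, nI, c.p_EI)
        preIE, postIE = _random_block(rng, nI, nE, c.p_IE)
        preII, postII = _random_block(rng, nI, nI, c.p_II, no_self=True)
        self.EE = _Block(preEE, postEE,
                         np.full(preEE.size, c.w_EE_init), nE)
        self.EI = _Block(preEI, postEI, np.full(preEI.size, c.w_EI), nE)
        self.IE = _Block(preIE, postIE,
                         np.full(preIE.size, c.w_IE_init), nI)
        self.II = _Block(preII, postII, np.full(preII.size, c.w_II), nI)
        n = nE + nI
        p = c.neuron
        self.u = np.full(n, p.u_rest)
        self.g_ahp = np.zeros(n)
        self.g_ampa = np.zeros(n)
        self.g_gaba = np.zeros(n)
        self.g_nmda_agg = np.zeros(n)       # external + E->I NMDA
        self.g_nmda_EE = np.zeros(preEE.size)  # per recurrent E->E synapse
        self.u_th = np.full(n, p.u_th_0)
        # plasticity traces
        self.x_plus = np.zeros(nE)       # presynaptic LTP trace (E neurons)
        self.y_E = np.zeros(nE)          # postsynaptic heterosynaptic trace
        self.y_minus = np.zeros(nE)      # postsynaptic LTD trace
        self.y_isp = np.zeros(nE)        # postsynaptic symmetric ISP trace
        self.x_isp = np.zeros(nI)        # presynaptic symmetric ISP trace
        self.e_tilde = np.zeros(preEE.size)
        self.I_trace = np.zeros(nE)
        dt = c.dt
        self._d = {
            "ampa": np.exp(-dt / p.tau_AMPA),
            "nmda": np.exp(-dt / p.tau_NMDA),
            "gaba": np.exp(-dt / p.tau_GABA),
            "ahp": np.exp(-dt / p.tau_AHP),
            "th": np.exp(-dt / p.tau_th),
            "plus": np.exp(-dt / c.esp.tau_plus),
            "minus": np.exp(-dt / c.esp.tau_minus),
            "yE": np.exp(-dt / c.esp.tau_ypost),
            "istdp": np.exp(-dt / c.isp.tau_iSTDP),
            "E": np.exp(-dt / c.esp.tau_E),
            "I": np.exp(-dt / c.isp.tau_I),
        }
        self._u_lo = min(p.E_GABA, p.E_AHP, p.u_reset)
        self._u_hi = max(p.E_NMDA, p.E_AMPA)
        self._ext_ref_n = int(round(c.tau_ref_ext / dt))
        self._ext_cool = np.zeros(n, dtype=np.int64)
        self.t = 0.0
        self.plastic = True

    # ------------------------------------------------------------------
    def _step(self, p_ext: np.ndarray, record_spikes=None) -> int:
        """One network step; returns the number of spikes this step."""
        c = self.c
        p = c.neuron
        dt = c.dt
        d = self._d
        nE = self.nE
        # 1) decays
        self.g_ampa *= d["ampa"]
        self.g_gaba *= d["gaba"]
        self.g_ahp *= d["ahp"]
        self.g_nmda_agg *= d["nmda"]
        self.g_nmda_EE *= d["nmda"]
        self.u_th = p.u_th_0 + (self.u_th - p.u_th_0) * d["th"]
        self.x_plus *= d["plus"]
        self.y_E *= d["yE"]
        self.y_minus *= d["minus"]
        self.y_isp *= d["istdp"]
        self.x_isp *= d["istdp"]
        # 2) external drive (AMPA + NMDA, refractory Bernoulli per neuron)
        ready = self._ext_cool == 0
        self._ext_cool[~ready] -= 1
        ext = ready & (self.rng.random(self.u.size) < p_ext)
        if ext.any():
            self._ext_cool[ext] = self._ext_ref_n
            self.g_ampa[ext] += c.w_ext
            self.g_nmda_agg[ext] += c.w_ext
        # 3) membrane update
        g_nmda_tot = self.g_nmda_agg.copy()
        g_nmda_tot[:nE] += np.bincount(self.EE.post, weights=self.g_nmda_EE,
                                       minlength=nE)
        h = mg_block(self.u, p.a_NMDA, p.b_NMDA, p.E_NMDA)
        u = self.u
        du = (-(u - p.u_rest)
              - self.g_ahp * (u - p.E_AHP)
              - self.g_ampa * (u - p.E_AMPA)
              - self.g_gaba * (u - p.E_GABA)
              - g_nmda_tot * h * (u - p.E_NMDA)) * (dt / p.tau_m)
        u = u + du
        # the exact solution is confined to the reversal-potential hull;
        # clamping keeps forward Euler stable in high-conductance episodes
        np.clip(u, self._u_lo, self._u_hi, out=u)
        spk = u >= self.u_th
        n_spk = int(spk.sum())
        if n_spk:
            u[spk] = p.u_reset
            self.u_th[spk] = p.u_th_star
            self.g_ahp[spk] += p.A_AHP
        self.u = u
        spkE = spk[:nE]
        spkI = spk[nE:]
        # 4) plasticity (pre-jump traces, current traces from last step)
        if self.plastic and n_spk:
            esp, isp = c.esp, c.isp
            Etot = np.bincount(self.EE.post, weights=self.e_tilde,
                               minlength=nE)
            gate = inhibitory_gate(self.I_trace, esp.I_star, esp.gamma,
                                   esp.I_th)
            if spkE.any():
                # LTP + heterosynaptic on synapses onto spiking E neurons
                m = spkE[self.EE.post]
                post_m = self.EE.post[m]
                E_syn = Etot[post_m]
                self.EE.w[m] += gate[post_m] * (
                    esp.A_LTP * self.x_plus[self.EE.pre[m]] * E_syn
                    - esp.A_het * self.y_E[post_m] * E_syn ** 2)
                # LTD on synapses from spiking E neurons
                mp = spkE[self.EE.pre]
                post_p = self.EE.post[mp]
                self.EE.w[mp] -= (gate[post_p] * esp.A_LTD
                                  * self.y_minus[post_p] * self.EE.w[mp])
                np.clip(self.EE.w, esp.w_min, esp.w_max, out=self.EE.w)
                # ISP post-spike branch
                mi = spkE[self.IE.post]
                post_i = self.IE.post[mi]
                coef = (isp.A_ISP * Etot[post_i]
                        * (Etot[post_i] - isp.alpha * self.I_trace[post_i]))
                self.IE.w[mi] += coef * self.x_isp[self.IE.pre[mi]]
            if spkI.any():
                # ISP pre-spike branch
                mi = spkI[self.IE.pre]
                post_i = self.IE.post[mi]
                coef = (isp.A_ISP * Etot[post_i]
                        * (Etot[post_i] - isp.alpha * self.I_trace[post_i]))
                self.IE.w[mi] += coef * self.y_isp[post_i]
            np.clip(self.IE.w, isp.w_min, isp.w_max, out=self.IE.w)
        # 5) recurrent conductance jumps + trace jumps
        if spkE.any():
            idxE = np.flatnonzero(spkE)
            for j in idxE:
                # out-neighbors of one presynaptic neuron are unique, so
                # plain fancy-indexed accumulation is safe
                s = self.EE.out_slice(j)
                self.g_nmda_EE[s] += self.EE.w[s]
                self.g_ampa[self.EE.post[s]] += self.EE.w[s]
                s2 = self.EI.out_slice(j)
                tgt = self.EI.post[s2] + nE
                self.g_ampa[tgt] += self.EI.w[s2]
                self.g_nmda_agg[tgt] += self.EI.w[s2]
            self.x_plus[idxE] += 1.0
            self.y_E[idxE] += 1.0
            self.y_minus[idxE] += 1.0
            self.y_isp[idxE] += 1.0
        if spkI.any():
            idxI = np.flatnonzero(spkI)
            for j in idxI:
                s = self.IE.out_slice(j)
                self.g_gaba[self.IE.post[s]] += self.IE.w[s]
                s2 = self.II.out_slice(j)
                self.g_gaba[self.II.post[s2] + nE] += self.II.w[s2]
            self.x_isp[idxI] += 1.0
        # 6) current traces (E neurons)
        u_post = self.u[self.EE.post]
        h_post = mg_block(u_post, p.a_NMDA, p.b_NMDA, p.E_NMDA)
        target_e = -self.g_nmda_EE * h_post * (u_post - p.E_NMDA)
        self.e_tilde = target_e + (self.e_tilde - target_e) * d["E"]
        target_i = self.g_gaba[:nE] * (self.u[:nE] - p.E_GABA)
        self.I_trace = target_i + (self.I_trace - target_i) * d["I"]
        if record_spikes is not None and n_spk:
            for i in np.flatnonzero(spk):
                record_spikes[i].append(self.t)
        self.t += dt
        return n_spk

    # ------------------------------------------------------------------
    def run_learning_phase(self, T: Optional[float] = None,
                           record_every: Optional[float] = None) -> dict:
        """Simulate the learning drive schedule with plasticity active.

        ``T`` truncates the schedule (ms).  Aborts with a RuntimeError if
        the network goes silent for longer than the configured limit or
        all plastic excitatory weights saturate at their upper bound.
        Returns snapshot arrays (times, mean block weights, mean total
        E-current per neuron, population rate).
        """
        c = self.c
        dt = c.dt
        self.plastic = True
        remaining = T
        snaps = {"t": [], "w_EE_mean": [], "w_IE_mean": [], "E_total_mean": [],
                 "rate_hz": [], "EI_ratio": []}
        stride = int(round(record_every / dt)) if record_every else None
        silent_steps = 0
        silence_limit = int(round(c.silence_limit_ms / dt))
        k = 0
        spike_count = 0
        n = self.nE + self.nI
        warmup_until = self.t + c.plasticity_warmup_ms
        for duration, p_stage in c.drive_schedule:
            if remaining is not None:
                duration = min(duration, remaining)
            p_vec = np.zeros(n)
            p_vec[: self.nE] = p_stage  # drive targets excitatory neurons
            n_steps = int(round(duration / dt))
            for _ in range(n_steps):
                self.plastic = self.t >= warmup_until
                n_spk = self._step(p_vec)
                spike_count += n_spk
                silent_steps = 0 if n_spk else silent_steps + 1
                if silent_steps > silence_limit:
                    raise RuntimeError(
                        f"network silent for {c.silence_limit_ms} ms at "
                        f"t={self.t:.0f} ms")
                if k % 10_000 == 0 and np.all(self.EE.w >= self.c.esp.w_max):
                    raise RuntimeError("all E->E weights saturated at w_max")
                if stride and k % stride == 0:
                    Etot = np.bincount(self.EE.post, weights=self.e_tilde,
                                       minlength=self.nE)
                    snaps["t"].append(self.t)
                    snaps["w_EE_mean"].append(float(self.EE.w.mean()))
                    snaps["w_IE_mean"].append(float(self.IE.w.mean()))
                    snaps["E_total_mean"].append(float(Etot.mean()))
                    with np.errstate(divide="ignore", invalid="ignore"):
                        r = np.where(self.I_trace > 1e-6,
                                     Etot / self.I_trace, np.nan)
                    snaps["EI_ratio"].append(
                        float(np.nanmean(r)) if np.any(self.I_trace > 1e-6)
                        else np.nan)
                    snaps["rate_hz"].append(
                        1000.0 * spike_count / (stride * dt) / n)
                    spike_count = 0
                k += 1
            if remaining is not None:
                remaining -= duration
                if remaining <= 0:
                    break
        return {key: np.asarray(v) for key, v in snaps.items()}

    def mean_total_E(self) -> float:
        """Population mean of the per-neuron summed filtered NMDA current."""
        Etot = np.bincount(self.EE.post, weights=self.e_tilde,
                           minlength=self.nE)
        return float(Etot.mean())

    def measure_baseline(self, T: float, background_p: float = 0.0
                         ) -> np.ndarray:
        """Per-neuron firing rates (Hz) in the self-sustained state.

        Runs ``T`` ms with plasticity frozen.  ``background_p`` adds a
        weak keep-alive external drive (0 = fully self-sustained).
        """
        self.plastic = False
        counts = np.zeros(self.nE + self.nI)
        p_vec = np.zeros(self.nE + self.nI)
        p_vec[: self.nE] = background_p
        spikes = [[] for _ in range(self.nE + self.nI)]
        n_steps = int(round(T / self.c.dt))
        for _ in range(n_steps):
            self._step(p_vec, record_spikes=spikes)
        for i, s in enumerate(spikes):
            counts[i] = len(s)
        return 1000.0 * counts / T

    def run_recall_phase(self, pE: np.ndarray, pI: np.ndarray,
                         pre_ms: float = 500.0, stim_ms: float = 1000.0,
                         post_ms: float = 1000.0,
                         background_p: float = 0.0,
                         seed: Optional[int] = None) -> dict:
        """Probe the frozen network with an external stimulation pattern.

        No pattern input before/after the 1-s stimulation window; by
        default there is no external input at all outside the window
        (the network must be self-sustained).  ``background_p`` adds a
        weak keep-alive drive throughout (identical for every pattern,
        so pattern comparisons remain meaningful at scales where the
        self-sustained state is fragile).  Returns per-neuron spike
        times and the window boundaries.  Raises RuntimeError if
        activity dies before the stimulation starts.
        """
        self.plastic = False
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        n = self.nE + self.nI
        if pE.size != self.nE or pI.size != self.nI:
            raise ValueError("pattern size mismatch")
        spikes = [[] for _ in range(n)]
        dt = self.c.dt
        t0 = self.t
        zeros = np.zeros(n)
        zeros[: self.nE] = background_p
        stim = np.concatenate([pE, pI])
        stim[: self.nE] = np.maximum(stim[: self.nE], background_p)
        pre_spikes = 0
        for _ in range(int(round(pre_ms / dt))):
            pre_spikes += self._step(zeros, record_spikes=spikes)
        if pre_ms > 0 and pre_spikes == 0:
            raise RuntimeError("self-sustained activity died before stimulus")
        for _ in range(int(round(stim_ms / dt))):
            self._step(stim, record_spikes=spikes)
        for _ in range(int(round(post_ms / dt))):
            self._step(zeros, record_spikes=spikes)
        return {
            "spikes": [np.asarray(s) - t0 for s in spikes],
            "t_stim": (pre_ms, pre_ms + stim_ms),
            "T": pre_ms + stim_ms + post_ms,
        }

    def membrane_histogram(self, T: float, mode: str = "both",
                           bin_mV: float = 1.0, p_ext: float = 0.0,
                           neuron: int = 0):
        """Histogram of excitatory membrane potentials over ``T`` ms.

        ``mode='spatial'`` samples all excitatory neurons at the final
        step only, ``'temporal'`` one neuron over time, ``'both'`` all
        neurons over time.  Returns ``(counts, bin_edges)`` with 1-mV
        bins by default.  Plasticity state is left untouched.
        """
        if mode not in ("spatial", "temporal", "both"):
            raise ValueError("mode must be spatial|temporal|both")
        plastic = self.plastic
        self.plastic = False
        p_vec = np.zeros(self.nE + self.nI)
        p_vec[: self.nE] = p_ext
        edges = np.arange(self._u_lo, self._u_hi + bin_mV, bin_mV)
        counts = np.zeros(edges.size - 1)
        n_steps = int(round(T / self.c.dt))
        for k in range(n_steps):
            self._step(p_vec)
            if mode == "temporal":
                counts += np.histogram(self.u[neuron:neuron + 1],
                                       bins=edges)[0]
            elif mode == "both":
                counts += np.histogram(self.u[: self.nE], bins=edges)[0]
        if mode == "spatial":
            counts = np.histogram(self.u[: self.nE], bins=edges)[0]
        self.plastic = plastic
        return counts, edges

    # ------------------------------------------------------------------
    def weight_matrix(self, block: str) -> np.ndarray:
        """Dense weight matrix of a block, w[i, j] = weight from j to i."""
        b = {"EE": self.EE, "EI": self.EI, "IE": self.IE, "II": self.II}[block]
        n_pre = self.nE if block in ("EE", "EI") else self.nI
        n_post = self.nE if block in ("EE", "IE") else self.nI
        return b.dense(n_pre, n_post)

    def per_neuron_weight_summary(self) -> dict:
        """Mean E-input, E-output and I-input weight per excitatory neuron."""
        nE = self.nE
        e_in = np.zeros(nE)
        e_out = np.zeros(nE)
        i_in = np.zeros(nE)
        cnt_in = np.bincount(self.EE.post, minlength=nE)
        cnt_out = np.bincount(self.EE.pre, minlength=nE)
        cnt_i = np.bincount(self.IE.post, minlength=nE)
        sum_in = np.bincount(self.EE.post, weights=self.EE.w, minlength=nE)
        sum_out = np.bincount(self.EE.pre, weights=self.EE.w, minlength=nE)
        sum_i = np.bincount(self.IE.post, weights=self.IE.w, minlength=nE)
        np.divide(sum_in, cnt_in, out=e_in, where=cnt_in > 0)
        np.divide(sum_out, cnt_out, out=e_out, where=cnt_out > 0)
        np.divide(sum_i, cnt_i, out=i_in, where=cnt_i > 0)
        return {"e_input": e_in, "e_output": e_out, "i_input": i_in}


def build_network(config: RecurrentNetConfig) -> RecurrentNetwork:
    """Construct a network with reproducible random connectivity."""
    return RecurrentNetwork(config)


def compute_impact(baseline_rates: np.ndarray, weight_matrix: np.ndarray
                   ) -> np.ndarray:
    """Hypothetical impact of each neuron: baseline rate x total output.

    ``weight_matrix[i, j]`` is the weight from neuron j to neuron i, so
    the total output weight of j is the j-th column sum.
    """
    rates = np.asarray(baseline_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    w = np.asarray(weight_matrix, dtype=float)
    if w.shape[1] != rates.size:
        raise ValueError("weight matrix columns must match rate vector")
    return rates * w.sum(axis=0)
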