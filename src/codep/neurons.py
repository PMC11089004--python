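"""Conductance-based leaky integrate-and-fire neurons.

Two neuron models are provided: a single-compartment (point) LIF neuron
with AMPA, NMDA and GABA_A conductances plus an after-hyperpolarization
(AHP) current, and a two-layer neuron whose passive dendritic branches
host the synapses and couple to a spiking soma through a conductance set
by electrotonic distance.

Conventions
-----------
Voltages are in mV, times in ms.  Synaptic conductances are dimensionless
(the membrane equation is written relative to the leak conductance), so
synaptic "weights" are dimensionless conductance jumps.  External current
enters as R*I_ext in mV with R in MOhm and I_ext in nA.

The NMDA conductance is multiplied by a voltage-dependent magnesium-block
factor H(u) = 1 / (1 + a*exp(b*(u - E_NMDA))); with b < 0 the block is
released by depolarization.

Integration is forward Euler for the membrane potential (default step
0.1 ms).  Linear first-order decays (conductances, AHP, adaptive
threshold) use the exact per-step exponential factor, which is cheaper
than Euler and unconditionally stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "DendriticNeuronParams",
    "mg_block",
    "adaptive_refractory",
    "coupling_from_distance",
    "PointNeuron",
    "TwoLayerNeuron",
]


@dataclass
class NeuronParams:
    """Parameters of the conductance-based LIF neuron.

    Defaults follow common cortical-neuron choices; the magnesium-block
    parameters (``a_NMDA``, ``b_NMDA``) use the Jahr-Stevens
    parameterization at physiological Mg2+.
    """

    tau_m: float = 20.0          # membrane time constant (ms)
    u_rest: float = -70.0        # resting potential (mV)
    u_reset: float = -60.0       # reset potential (mV)
    R: float = 100.0             # input resistance (MOhm)
    E_AMPA: float = 0.0          # reversal potentials (mV)
    E_NMDA: float = 0.0
    E_GABA: float = -80.0
    E_AHP: float = -90.0
    tau_AMPA: float = 5.0        # conductance decay constants (ms)
    tau_NMDA: float = 50.0
    tau_GABA: float = 10.0
    tau_AHP: float = 100.0
    A_AHP: float = 0.15          # AHP conductance jump per spike
    a_NMDA: float = 0.28         # Mg-block scale (dimensionless)
    b_NMDA: float = -0.062       # Mg-block slope (1/mV)
    threshold_mode: str = "fixed"   # "fixed" | "adaptive"
    u_th: float = -50.0          # fixed threshold (mV)
    tau_ref: float = 2.0         # refractory period, fixed mode (ms)
    u_th_0: float = -50.0        # adaptive threshold baseline (mV)
    u_th_star: float = 20.0      # adaptive threshold right after a spike (mV)
    tau_th: float = 5.0          # adaptive threshold decay (ms)

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_AMPA", "tau_NMDA", "tau_GABA", "tau_AHP", "tau_th"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be >= 0")
        if self.a_NMDA < 0:
            raise ValueError("a_NMDA must be >= 0")
        if self.threshold_mode not in ("fixed", "adaptive"):
            raise ValueError("threshold_mode must be 'fixed' or 'adaptive'")
        if not (self.E_GABA <= self.u_rest < self.E_NMDA):
            raise ValueError("require E_GABA <= u_rest < E_NMDA")
        if self.threshold_mode == "fixed" and self.u_reset > self.u_th:
            raise ValueError("u_reset must not exceed u_th")
        if self.threshold_mode == "adaptive":
            if self.u_reset > self.u_th_0:
                raise ValueError("u_reset must not exceed u_th_0")
            if self.u_th_star < self.E_NMDA:
                raise ValueError(
                    "adaptive mode requires u_th_star >= E_NMDA "
                    "(refractory period otherwise undefined)"
                )

    def with_(self, **kwargs) -> "NeuronParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class DendriticNeuronParams:
    """Two-layer neuron: a spiking soma coupled to passive branches.

    ``J`` holds the per-branch soma-dendrite coupling conductance
    (dimensionless, relative to leak).  ``d_star`` is the distance scale
    of the coupling law J = (d_star/d)**2.
    """

    neuron: NeuronParams = field(default_factory=NeuronParams)
    J: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    d_star: float = 50.0  # um

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 1 or self.J.size < 1:
            raise ValueError("J must be a 1-D array with >= 1 branch")
        if np.any(self.J < 0):
            raise ValueError("couplings J must be >= 0")
        if self.d_star <= 0:
            raise ValueError("d_star must be > 0")

    @property
    def n_branches(self) -> int:
        return self.J.size


def mg_block(u, a_NMDA: float = 0.28, b_NMDA: float = -0.062,
             E_NMDA: float = 0.0):
    """Voltage-dependent magnesium-block factor of the NMDA conductance.

    H(u) = 1 / (1 + a_NMDA * exp(b_NMDA * (u - E_NMDA))), in (0, 1].
    With b_NMDA < 0 the factor increases with depolarization (the block
    is released).  Accepts scalars or arrays.
    """
    if a_NMDA < 0:
        raise ValueError("a_NMDA must be >= 0")
    u = np.asarray(u, dtype=float)
    out = 1.0 / (1.0 + a_NMDA * np.exp(b_NMDA * (u - E_NMDA)))
    return float(out) if out.ndim == 0 else out


def adaptive_refractory(params: NeuronParams) -> float:
    """Absolute refractory period implied by the adaptive threshold.

    After a spike the threshold starts at ``u_th_star`` and decays toward
    ``u_th_0``; the membrane potential cannot exceed E_NMDA, so no spike
    can occur until the threshold has decayed to E_NMDA:

        tau_ref = tau_th * ln[(u_th_star - u_th_0) / (E_NMDA - u_th_0)]
    """
    if params.u_th_star < params.E_NMDA:
        raise ValueError("u_th_star must be >= E_NMDA")
    if params.E_NMDA <= params.u_th_0:
        raise ValueError("require E_NMDA > u_th_0")
    return params.tau_th * np.log(
        (params.u_th_star - params.u_th_0) / (params.E_NMDA - params.u_th_0)
    )


def coupling_from_distance(d, d_star: float):
    """Soma-dendrite coupling J and attenuation a from electrotonic distance.

    J = d_star**2 / d**2 and a = J / (1 + J): a steady somatic
    depolarization is attenuated by a factor ``a`` at the branch.
    Accepts scalar or array distances (um); returns ``(J, a)``.
    """
    if d_star <= 0:
        raise ValueError("d_star must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be > 0")
    J = d_star ** 2 / d ** 2
    a = J / (1.0 + J)
    if J.ndim == 0:
        return float(J), float(a)
    return J, a


class PointNeuron:
    """Single-compartment conductance-based LIF neuron.

    Tracks per-synapse NMDA conductances (needed by the plasticity
    traces) and aggregate AMPA/GABA_A conductances.  Excitatory events
    increment both the AMPA aggregate and the synapse's NMDA conductance
    by the synaptic weight.

    Per-step update order: (1) exponential decay of conductances, AHP and
    adaptive threshold, (2) presynaptic conductance jumps, (3) forward
    Euler step of u (clamped at u_reset during the fixed-mode refractory
    period), (4) threshold test, reset and AHP jump.
    """

    def __init__(self, params: NeuronParams, n_exc: int = 0, n_inh: int = 0,
                 dt: float = 0.1):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.p = params
        self.dt = dt
        self.n_exc = n_exc
        self.n_inh = n_inh
        self.u = params.u_rest
        self.g_ahp = 0.0
        self.g_ampa = 0.0
        self.g_gaba = 0.0
        self.g_nmda = np.zeros(n_exc)
        self.u_th_t = params.u_th_0
        self._ref_steps = 0
        self._ref_n = int(round(params.tau_ref / dt))
        self._d_ampa = np.exp(-dt / params.tau_AMPA)
        self._d_nmda = np.exp(-dt / params.tau_NMDA)
        self._d_gaba = np.exp(-dt / params.tau_GABA)
        self._d_ahp = np.exp(-dt / params.tau_AHP)
        self._d_th = np.exp(-dt / params.tau_th)
        self._u_lo = min(params.E_GABA, params.E_AHP, params.u_reset)
        self._u_hi = max(params.E_NMDA, params.E_AMPA)

    @property
    def g_nmda_total(self) -> float:
        return float(self.g_nmda.sum())

    def step(self, exc_jumps=None, inh_jump: float = 0.0,
             I_ext: float = 0.0) -> bool:
        """Advance one time step; returns True if the neuron spiked.

        ``exc_jumps``: per-synapse conductance increments (array of length
        n_exc, zero where no presynaptic spike); ``inh_jump``: summed
        GABA_A conductance increment this step.
        """
        p = self.p
        if not np.isfinite(self.u):
            raise FloatingPointError("membrane potential is not finite")
        # (1) decay
        self.g_ampa *= self._d_ampa
        self.g_gaba *= self._d_gaba
        self.g_ahp *= self._d_ahp
        if self.n_exc:
            self.g_nmda *= self._d_nmda
        if p.threshold_mode == "adaptive":
            self.u_th_t = p.u_th_0 + (self.u_th_t - p.u_th_0) * self._d_th
        # (2) jumps
        if exc_jumps is not None:
            self.g_nmda += exc_jumps
            self.g_ampa += float(np.sum(exc_jumps))
        if inh_jump:
            self.g_gaba += inh_jump
        # (3) integrate
        u = self.u
        if self.p.threshold_mode == "fixed" and self._ref_steps > 0:
            self._ref_steps -= 1
            self.u = p.u_reset
            return False
        h = mg_block(u, p.a_NMDA, p.b_NMDA, p.E_NMDA)
        du = (
            -(u - p.u_rest)
            - self.g_ahp * (u - p.E_AHP)
            - self.g_ampa * (u - p.E_AMPA)
            - self.g_gaba * (u - p.E_GABA)
            - self.g_nmda_total * h * (u - p.E_NMDA)
            + p.R * I_ext
        ) * (self.dt / p.tau_m)
        u = u + du
        if I_ext == 0.0:
            # exact solution is confined to the reversal-potential hull;
            # clamping keeps forward Euler stable at high conductance
            u = min(max(u, self._u_lo), self._u_hi)
        # (4) threshold
        threshold = p.u_th if p.threshold_mode == "fixed" else self.u_th_t
        spiked = u >= threshold
        if spiked:
            u = p.u_reset
            self.g_ahp += p.A_AHP
            if p.threshold_mode == "fixed":
                self._ref_steps = self._ref_n
            else:
                self.u_th_t = p.u_th_star
        self.u = u
        return bool(spiked)


class TwoLayerNeuron:
    """Spiking soma fed by passive dendritic branches.

    Synaptic input targets the branches only; the soma integrates leak,
    AHP and the coupling currents J_i*(u_soma - u_i).  Branches integrate
    leak, their synaptic conductances and the reciprocal coupling
    J_i*(u_i - u_soma); they never emit spikes, but NMDA plateaus arise
    from the Mg-block nonlinearity because branches have no threshold.
    The soma spikes with the fixed-threshold rule (reset + clamp).
    """

    def __init__(self, params: DendriticNeuronParams,
                 n_exc_per_branch, n_inh_per_branch, dt: float = 0.1):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.p = params
        n_b = params.n_branches
        n_exc_per_branch = list(n_exc_per_branch)
        n_inh_per_branch = list(n_inh_per_branch)
        if len(n_exc_per_branch) != n_b or len(n_inh_per_branch) != n_b:
            raise ValueError("per-branch synapse counts must match n_branches")
        self.dt = dt
        np_ = params.neuron
        self.u_soma = np_.u_rest
        self.u = np.full(n_b, np_.u_rest)  # branch potentials
        self.g_ahp = 0.0
        self.g_ampa = np.zeros(n_b)
        self.g_gaba = np.zeros(n_b)
        self.g_nmda = [np.zeros(n) for n in n_exc_per_branch]
        self.n_exc_per_branch = n_exc_per_branch
        self.n_inh_per_branch = n_inh_per_branch
        self._ref_steps = 0
        self._ref_n = int(round(np_.tau_ref / dt))
        self._d_ampa = np.exp(-dt / np_.tau_AMPA)
        self._d_nmda = np.exp(-dt / np_.tau_NMDA)
        self._d_gaba = np.exp(-dt / np_.tau_GABA)
        self._d_ahp = np.exp(-dt / np_.tau_AHP)

    def step(self, exc_jumps_per_branch=None, inh_jumps_per_branch=None,
             I_ext_soma: float = 0.0, clamp_soma=None) -> bool:
        """Advance one step; returns True if the soma spiked.

        ``exc_jumps_per_branch``: sequence of per-synapse NMDA/AMPA jump
        arrays (or None) per branch; ``inh_jumps_per_branch``: sequence
        of summed GABA_A jumps per branch.  ``clamp_soma`` holds the
        somatic potential at a fixed value (voltage clamp).
        """
        p = self.p.neuron
        J = self.p.J
        # (1) decay
        self.g_ampa *= self._d_ampa
        self.g_gaba *= self._d_gaba
        self.g_ahp *= self._d_ahp
        for g in self.g_nmda:
            g *= self._d_nmda
        # (2) jumps
        if exc_jumps_per_branch is not None:
            for i, jumps in enumerate(exc_jumps_per_branch):
                if jumps is not None:
                    self.g_nmda[i] += jumps
                    self.g_ampa[i] += float(np.sum(jumps))
        if inh_jumps_per_branch is not None:
            for i, jump in enumerate(inh_jumps_per_branch):
                if jump:
                    self.g_gaba[i] += jump
        # (3) integrate branches then soma (both from pre-step potentials)
        us = self.u_soma
        u = self.u
        h = mg_block(u, p.a_NMDA, p.b_NMDA, p.E_NMDA)
        g_nmda_tot = np.array([g.sum() for g in self.g_nmda])
        du = (
            -(u - p.u_rest)
            - J * (u - us)
            - self.g_ampa * (u - p.E_AMPA)
            - self.g_gaba * (u - p.E_GABA)
            - g_nmda_tot * h * (u - p.E_NMDA)
        ) * (self.dt / p.tau_m)
        self.u = np.clip(u + du, min(p.E_GABA, p.E_AHP, p.u_reset),
                         max(p.E_NMDA, p.E_AMPA))
        spiked = False
        if clamp_soma is not None:
            self.u_soma = float(clamp_soma)
        elif self._ref_steps > 0:
            self._ref_steps -= 1
            self.u_soma = p.u_reset
        else:
            dus = (
                -(us - p.u_rest)
                - self.g_ahp * (us - p.E_AHP)
                - float(np.sum(J * (us - u)))
                + p.R * I_ext_soma
            ) * (self.dt / p.tau_m)
            us = us + dus
            if us >= p.u_th:
                us = p.u_reset
                self.g_ahp += p.A_AHP
                self._ref_steps = self._ref_n
                spiked = True
            self.u_soma = us
        return spiked
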