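"""Co-dependent excitatory and inhibitory synaptic plasticity.

Excitatory synapses follow an STDP-like rule whose potentiation scales
linearly, and whose heterosynaptic weakening scales quadratically, with a
low-pass filtered record of neighboring NMDA currents (the E trace); the
whole excitatory rule is multiplicatively gated by a filtered record of
local GABA_A currents (the I trace), so excitatory weights can only move
while the synapse is disinhibited.  Inhibitory synapses follow a
symmetric STDP window scaled by E*(E - alpha*I), pushing the local
excitation/inhibition ratio toward the setpoint alpha.

Event semantics (per simulation step, after the neuron update):

* postsynaptic spike:  w_j += gate * (A_LTP * x+_j * E_j
                                      - A_het * yE_post * E_j**2)   (all j)
* presynaptic spike j: w_j -= gate * A_LTD * y-_post * w_j
* inhibitory pre spike k: w_k += A_ISP * E * (E - alpha*I) * y_post
* postsynaptic spike:     w_k += A_ISP * E * (E - alpha*I) * x_k    (all k)

Spike traces are read *before* the triggering spike's own increment
(standard STDP convention, prevents self-pairing), and decay with exact
per-step exponential factors so that isolated spike pairs reproduce the
closed-form pairwise weight changes (see ``codep.analytics``) to machine
precision.  Weights are hard-clipped to their bounds after every update.

The neighborhood trace E_j is a distance-weighted sum of per-synapse
filtered NMDA currents.  When no synapse positions are given (or
sigma = inf) all synapses on the compartment are neighbors with equal
weight and E_j reduces to the plain sum of the filtered currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ESPParams",
    "ISPParams",
    "DistanceKernel",
    "CoTraceState",
    "build_distance_kernel",
    "inhibitory_gate",
    "esp_apply",
    "isp_apply",
]

_LN1000 = float(np.log(1e3))


@dataclass
class ESPParams:
    """Parameters of the co-dependent excitatory plasticity rule.

    Learning rates carry units of weight per (trace unit): the LTP term
    is linear in the E trace (mV), the heterosynaptic term quadratic in
    it, and LTD is proportional to the current weight.  ``I_star`` and
    ``gamma`` shape the inhibitory gate exp[-(I/I*)**gamma]; above
    ``I_th`` the gate is exactly zero (hard block).  By default I_th is
    placed where the gate falls below 1e-3, making the hard block
    numerically seamless.
    """

    A_LTP: float = 3e-3
    A_het: float = 2e-5
    A_LTD: float = 2e-3
    tau_plus: float = 17.0      # presynaptic LTP trace (ms)
    tau_minus: float = 34.0     # postsynaptic LTD trace (ms)
    tau_ypost: float = 50.0     # postsynaptic heterosynaptic trace (ms)
    tau_E: float = 1000.0       # NMDA-current filter (ms)
    I_star: float = 1.0         # inhibitory gate scale (trace units, mV)
    gamma: float = 2.0          # gate exponent
    I_th: Optional[float] = None  # hard-block threshold; default from I_star
    w_min: float = 1e-5
    w_max: float = 10.0
    sigma: float = np.inf       # kernel width (synapse-distance units)

    def __post_init__(self) -> None:
        for name in ("A_LTP", "A_het", "A_LTD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_plus", "tau_minus", "tau_ypost", "tau_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.I_star <= 0 or self.gamma <= 0:
            raise ValueError("I_star and gamma must be > 0")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")
        if self.I_th is None:
            self.I_th = self.I_star * _LN1000 ** (1.0 / self.gamma)
        if self.I_th < self.I_star:
            raise ValueError("I_th must be >= I_star")

    def with_(self, **kwargs) -> "ESPParams":
        kwargs.setdefault("I_th", None)
        return replace(self, **kwargs)


@dataclass
class ISPParams:
    """Parameters of the co-dependent inhibitory plasticity rule."""

    A_ISP: float = 1e-4
    alpha: float = 1.0          # EI balance setpoint
    tau_iSTDP: float = 20.0     # symmetric STDP window (ms)
    tau_I: float = 100.0        # GABA_A-current filter (ms)
    w_min: float = 1e-5
    w_max: float = 70.0

    def __post_init__(self) -> None:
        if self.A_ISP < 0:
            raise ValueError("A_ISP must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tau_iSTDP <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be > 0")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")

    def with_(self, **kwargs) -> "ISPParams":
        return replace(self, **kwargs)


@dataclass
class DistanceKernel:
    """Distance-dependent interaction matrix between excitatory synapses.

    ``F[i, j]`` weighs the contribution of the filtered NMDA current of
    synapse j to the neighborhood trace of synapse i:

        F[i, j] = exp(-0.5 (dx_ij / sigma)**2)
                  / ((1/N) * sum_k exp(-0.5 (dx_ik / sigma)**2))

    The row normalization makes the population average of the
    neighborhood traces approximately equal to N times the mean filtered
    current, independent of sigma.  ``F is None`` encodes the
    all-to-all (sigma = inf) shortcut E_j = sum_k Etilde_k.
    """

    sigma: float
    positions: Optional[np.ndarray] = None
    F: Optional[np.ndarray] = None

    def apply(self, e_tilde: np.ndarray) -> np.ndarray:
        if self.F is None:
            return np.full_like(e_tilde, e_tilde.sum())
        return self.F @ e_tilde


def build_distance_kernel(positions, sigma: float) -> DistanceKernel:
    """Build the Gaussian distance kernel over 1-D synapse positions.

    ``sigma = inf`` selects the all-to-all shortcut (no matrix is
    stored).  ``sigma -> 0`` gives a diagonal kernel with F[i,i] = N
    (requires distinct positions).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or positions.size < 1:
        raise ValueError("positions must be a non-empty 1-D array")
    if sigma <= 0:
        raise ValueError("sigma must be > 0 (use np.inf for all-to-all)")
    if np.isinf(sigma):
        return DistanceKernel(sigma=np.inf, positions=positions, F=None)
    dx = positions[:, None] - positions[None, :]
    g = np.exp(-0.5 * (dx / sigma) ** 2)
    norm = g.mean(axis=1)  # (1/N) sum_k over columns for each row i
    if np.any(norm <= 0):
        raise ValueError("kernel normalization vanished; sigma too small")
    return DistanceKernel(sigma=sigma, positions=positions, F=g / norm[:, None])


def inhibitory_gate(I_trace, I_star: float, gamma: float, I_th: float):
    """Multiplicative inhibitory gate on excitatory plasticity.

    exp[-(I/I*)**gamma] for I <= I_th and exactly 0 above I_th.
    Monotone nonincreasing in I; gate(0) = 1.  Accepts scalars/arrays.
    """
    I = np.asarray(I_trace, dtype=float)
    g = np.exp(-np.power(np.maximum(I, 0.0) / I_star, gamma))
    g = np.where(I > I_th, 0.0, g)
    return float(g) if g.ndim == 0 else g


@dataclass
class CoTraceState:
    """Per-synapse plasticity traces for one postsynaptic compartment.

    Spike traces: ``x_plus`` (per excitatory synapse, LTP), ``y_post_E``
    and ``y_post_minus`` (postsynaptic; heterosynaptic and LTD), and the
    symmetric ISP pair ``x_isp`` (per inhibitory synapse) / ``y_post``.
    Current traces: ``e_tilde`` (per-synapse filtered NMDA current, mV),
    ``E`` (kernel-weighted neighborhood trace, mV) and the scalar
    ``I`` (filtered GABA_A current, mV).
    """

    n_exc: int
    n_inh: int
    dt: float
    esp: ESPParams
    isp: ISPParams = field(default_factory=ISPParams)
    kernel: Optional[DistanceKernel] = None

    def __post_init__(self) -> None:
        self.x_plus = np.zeros(self.n_exc)
        self.y_post_E = 0.0
        self.y_post_minus = 0.0
        self.y_post = 0.0
        self.x_isp = np.zeros(self.n_inh)
        self.e_tilde = np.zeros(self.n_exc)
        self.E = np.zeros(self.n_exc)
        self.I = 0.0
        dt = self.dt
        self._d_plus = float(np.exp(-dt / self.esp.tau_plus))
        self._d_minus = float(np.exp(-dt / self.esp.tau_minus))
        self._d_ypost = float(np.exp(-dt / self.esp.tau_ypost))
        self._d_isp = float(np.exp(-dt / self.isp.tau_iSTDP))
        self._d_E = float(np.exp(-dt / self.esp.tau_E))
        self._d_I = float(np.exp(-dt / self.isp.tau_I))

    # -- spike traces -------------------------------------------------
    def decay_spike_traces(self) -> None:
        """Exact exponential decay, applied once per step before events."""
        self.x_plus *= self._d_plus
        self.y_post_E *= self._d_ypost
        self.y_post_minus *= self._d_minus
        self.y_post *= self._d_isp
        self.x_isp *= self._d_isp

    def jump_spike_traces(self, pre_exc=None, pre_inh=None,
                          post_spiked: bool = False) -> None:
        """Unit increments for this step's spikes (after plasticity)."""
        if pre_exc is not None:
            self.x_plus[pre_exc] += 1.0
        if pre_inh is not None:
            self.x_isp[pre_inh] += 1.0
        if post_spiked:
            self.y_post_E += 1.0
            self.y_post_minus += 1.0
            self.y_post += 1.0

    # -- current traces -----------------------------------------------
    def update_currents(self, u: float, g_nmda: np.ndarray,
                        g_gaba_total: float, h_u: Optional[float] = None,
                        a_NMDA: float = 0.28, b_NMDA: float = -0.062,
                        E_NMDA: float = 0.0, E_GABA: float = -80.0) -> None:
        """Relax e_tilde and I toward this step's synaptic currents.

        The NMDA source term is -g_NMDA_j * H(u) * (u - E_NMDA) >= 0 for
        u < E_NMDA; the GABA_A source is g_GABA_tot * (u - E_GABA) >= 0
        for u > E_GABA.  Exact exponential relaxation toward the
        instantaneous target keeps both traces nonnegative for any dt.
        """
        if h_u is None:
            h_u = 1.0 / (1.0 + a_NMDA * np.exp(b_NMDA * (u - E_NMDA)))
        target_e = -g_nmda * h_u * (u - E_NMDA)
        self.e_tilde = target_e + (self.e_tilde - target_e) * self._d_E
        target_i = g_gaba_total * (u - E_GABA)
        self.I = target_i + (self.I - target_i) * self._d_I
        if self.kernel is not None:
            self.E = self.kernel.apply(self.e_tilde)
        else:
            self.E = np.full(self.n_exc, self.e_tilde.sum())

    @property
    def E_total(self) -> float:
        """Compartment-wide excitatory trace (sum of filtered currents)."""
        return float(self.e_tilde.sum())

    def gate(self) -> float:
        return inhibitory_gate(self.I, self.esp.I_star, self.esp.gamma,
                               self.esp.I_th)


def esp_apply(weights: np.ndarray, traces: CoTraceState,
              pre_exc=None, post_spiked: bool = False,
              esp: Optional[ESPParams] = None) -> np.ndarray:
    """One step of the excitatory rule; modifies ``weights`` in place.

    ``pre_exc``: indices of excitatory synapses with a presynaptic spike
    this step.  Traces must be in their pre-jump state.  Simultaneous pre
    and post events apply the LTP/heterosynaptic branch first, then LTD,
    both with pre-jump traces.
    """
    esp = esp or traces.esp
    g = traces.gate()
    if g == 0.0:
        return weights
    if post_spiked:
        weights += g * (esp.A_LTP * traces.x_plus * traces.E
                        - esp.A_het * traces.y_post_E * traces.E ** 2)
    if pre_exc is not None and len(pre_exc) > 0 and traces.y_post_minus > 0:
        weights[pre_exc] -= (g * esp.A_LTD * traces.y_post_minus
                             * weights[pre_exc])
    np.clip(weights, esp.w_min, esp.w_max, out=weights)
    return weights


def isp_apply(weights: np.ndarray, traces: CoTraceState,
              pre_inh=None, post_spiked: bool = False,
              isp: Optional[ISPParams] = None) -> np.ndarray:
    """One step of the inhibitory rule; modifies ``weights`` in place.

    The rule's E variable is the compartment-wide sum of filtered NMDA
    currents (all synapses on the compartment are neighbors).
    """
    isp = isp or traces.isp
    E = traces.E_total
    if E == 0.0:
        return weights
    c = isp.A_ISP * E * (E - isp.alpha * traces.I)
    changed = False
    if pre_inh is not None and len(pre_inh) > 0 and traces.y_post > 0:
        weights[pre_inh] += c * traces.y_post
        changed = True
    if post_spiked:
        weights += c * traces.x_isp
        changed = True
    if changed:
        np.clip(weights, isp.w_min, isp.w_max, out=weights)
    return weights
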