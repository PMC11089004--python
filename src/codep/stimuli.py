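"""Synthetic presynaptic input generation.

All stochastic inputs derive from a per-step Bernoulli process with an
absolute refractory period: in every time step of length dt a source
fires with probability p(t) unless it spiked within the preceding
tau_ref.  For constant p the mean rate follows the closed form

    nu = (1/dt) * p * (1 - p)**(tau_ref/dt)        [Hz, dt and tau_ref in ms]

Pathway inputs modulate p(t) with a rectified Ornstein-Uhlenbeck process
shared by all afferents of a pathway, producing within-pathway rate
correlations.  Learning windows and recall stimulation patterns replace
the per-afferent probabilities over defined intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "BernoulliRateSpec",
    "PathwaySpec",
    "LearningWindowSpec",
    "RecallStimulusSpec",
    "SpikeTrain",
    "rate_from_prob",
    "gen_bernoulli_trains",
    "BernoulliSpiker",
    "OUPathways",
    "gen_ou_pathways",
    "apply_learning_window",
    "build_recall_pattern",
    "spike_trains_to_frame",
]


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) of one source."""

    source_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class BernoulliRateSpec:
    p: float = 0.002           # per-step spike probability
    dt: float = 0.1            # step (ms)
    tau_ref: float = 5.0       # generator refractory (ms)
    T: float = 1000.0          # duration (ms)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.tau_ref < 0 or self.dt <= 0:
            raise ValueError("tau_ref >= 0 and dt > 0 required")


@dataclass
class PathwaySpec:
    """Groups of correlated afferents driven by a shared OU-modulated rate."""

    n_pathways: int = 8
    n_exc_per_pathway: int = 100
    n_inh_per_pathway: int = 25
    p_bg_exc: float = 2e-4     # background per-step probabilities
    p_bg_inh: float = 4e-4
    p_star: float = 0.025      # fluctuation amplitude
    tau_OU: float = 50.0       # OU time constant (ms)
    tau_ref_exc: float = 5.0
    tau_ref_inh: float = 2.5
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_bg_exc", "p_bg_inh", "p_star"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class LearningWindowSpec:
    """Transient disinhibition window with pathway-specific activation.

    During the first ``background_ms`` all excitatory afferents fire at
    background; during the final ``active_ms`` pathway mu fires with
    probability alpha_mu[mu] * p_active.  Inhibitory afferents stay at
    constant background for the whole window (disinhibition: the OU
    modulation is removed).
    """

    t_start: float
    alpha_mu: Sequence[float]
    background_ms: float = 500.0
    active_ms: float = 200.0
    p_active: float = 0.005

    def __post_init__(self) -> None:
        self.alpha_mu = np.asarray(self.alpha_mu, dtype=float)
        if np.any(self.alpha_mu < 0) or np.any(self.alpha_mu > 1):
            raise ValueError("alpha_mu entries must be in [0, 1]")

    @property
    def duration(self) -> float:
        return self.background_ms + self.active_ms

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


# Pathway activation vectors of the two learning windows of the
# receptive-field protocol: window 1 peaks at pathway 6, window 2 at 4.
WINDOW1_ALPHA = (0.15, 0.2, 0.3, 0.4, 0.6, 0.8, 0.6, 0.4)
WINDOW2_ALPHA = (0.3, 0.4, 0.6, 0.8, 0.6, 0.4, 0.3, 0.2)


@dataclass
class RecallStimulusSpec:
    """External stimulation pattern for the recurrent-network recall phase."""

    kind: str = "ordered"          # ordered | partial_shuffle | random
    shuffle_fraction: float = 0.75
    pE_max: float = 0.5
    pI_max: float = 0.25           # 0.25 for ordered ramp; random part uses 0.4
    pI_rand_max: float = 0.4
    duration: float = 1000.0       # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ordered", "partial_shuffle", "random"):
            raise ValueError("kind must be ordered|partial_shuffle|random")
        if not 0.0 <= self.shuffle_fraction <= 1.0:
            raise ValueError("shuffle_fraction must be in [0, 1]")


def rate_from_prob(p: float, dt: float, tau_ref: float) -> float:
    """Mean rate (Hz) of the refractory Bernoulli process, closed form.

    nu = (1/dt) * p * (1-p)**n with n = round(tau_ref/dt); dt and tau_ref
    in ms, so the leading factor 1/dt is converted from 1/ms to Hz.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("p must be in [0, 1)")
    if dt <= 0 or tau_ref < 0:
        raise ValueError("dt > 0 and tau_ref >= 0 required")
    n = int(round(tau_ref / dt))
    return 1000.0 / dt * p * (1.0 - p) ** n


def gen_bernoulli_trains(spec: BernoulliRateSpec, n_sources: int):
    """Independent constant-rate refractory Bernoulli spike trains.

    Inter-spike intervals are sampled exactly as n_ref + Geometric(p)
    steps, equivalent to the per-step draw but much faster for long
    durations.  Returns a list of :class:`SpikeTrain`.
    """
    rng = np.random.default_rng(spec.seed)
    n_ref = int(round(spec.tau_ref / spec.dt))
    n_steps = int(round(spec.T / spec.dt))
    trains = []
    for sid in range(n_sources):
        if spec.p == 0.0:
            trains.append(SpikeTrain(sid, np.empty(0)))
            continue
        # expected spike count + safety margin
        exp_n = int(n_steps * spec.p / (1.0 + spec.p * n_ref)) + 1
        steps = []
        t = 0
        while t < n_steps:
            block = rng.geometric(spec.p, size=max(exp_n, 16)) + n_ref
            for isi in block:
                t += int(isi)
                if t >= n_steps:
                    break
                steps.append(t)
            else:
                continue
            break
        trains.append(SpikeTrain(sid, np.asarray(steps, dtype=float) * spec.dt))
    return trains


class BernoulliSpiker:
    """Online per-step spike generation for n sources with refractory.

    ``step(p)`` takes the per-source spike probabilities for this step
    (scalar or array) and returns the indices of spiking sources.
    """

    def __init__(self, n: int, tau_ref, dt: float, rng: np.random.Generator):
        self.n = n
        self.dt = dt
        self.rng = rng
        tau_ref = np.broadcast_to(np.asarray(tau_ref, dtype=float), (n,))
        self._ref_n = np.rint(tau_ref / dt).astype(np.int64)
        self._cooldown = np.zeros(n, dtype=np.int64)

    def step(self, p) -> np.ndarray:
        ready = self._cooldown == 0
        self._cooldown[~ready] -= 1
        draws = self.rng.random(self.n)
        spk = np.flatnonzero(ready & (draws < p))
        self._cooldown[spk] = self._ref_n[spk]
        return spk


class OUPathways:
    """Shared Ornstein-Uhlenbeck rate modulation per pathway.

    dy/dt = -y/tau_OU + xi(t) integrated by Euler-Maruyama with
    increment xi*sqrt(dt) (unit diffusion coefficient); the per-afferent
    probability is p(t) = p_star * max(y_mu, 0) + p_bg.
    """

    def __init__(self, spec: PathwaySpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.y = np.zeros(spec.n_pathways)

    def step(self) -> np.ndarray:
        s = self.spec
        noise = self.rng.standard_normal(s.n_pathways)
        self.y += -self.y * (s.dt / s.tau_OU) + noise * np.sqrt(s.dt)
        return self.y

    def probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """Current per-afferent (exc, inh) spike probabilities."""
        s = self.spec
        p_mu = s.p_star * np.maximum(self.y, 0.0)
        p_exc = np.repeat(p_mu, s.n_exc_per_pathway) + s.p_bg_exc
        p_inh = np.repeat(p_mu, s.n_inh_per_pathway) + s.p_bg_inh
        return p_exc, p_inh

    @property
    def stationary_std(self) -> float:
        """Closed-form stationary s.d. of the discretized OU path."""
        s = self.spec
        a = 1.0 - s.dt / s.tau_OU
        return float(np.sqrt(s.dt / (1.0 - a * a)))


def gen_ou_pathways(spec: PathwaySpec, T: float,
                    windows: Sequence[LearningWindowSpec] = (),
                    record_probs: bool = False):
    """Generate pathway spike trains (and optionally probability traces).

    Returns ``(exc_trains, inh_trains, prob_traces)`` where the trains
    are lists of :class:`SpikeTrain` and ``prob_traces`` is an
    (n_steps, n_pathways) array of the excitatory pathway probabilities
    (None unless requested).
    """
    rng = np.random.default_rng(spec.seed)
    ou = OUPathways(spec, rng)
    n_exc = spec.n_pathways * spec.n_exc_per_pathway
    n_inh = spec.n_pathways * spec.n_inh_per_pathway
    exc_spk = BernoulliSpiker(n_exc, spec.tau_ref_exc, spec.dt, rng)
    inh_spk = BernoulliSpiker(n_inh, spec.tau_ref_inh, spec.dt, rng)
    n_steps = int(round(T / spec.dt))
    exc_times = [[] for _ in range(n_exc)]
    inh_times = [[] for _ in range(n_inh)]
    probs = np.empty((n_steps, spec.n_pathways)) if record_probs else None
    _check_windows(windows, T)
    for k in range(n_steps):
        t = k * spec.dt
        ou.step()
        p_exc, p_inh = ou.probabilities()
        p_exc, p_inh = apply_learning_window(p_exc, p_inh, t, spec, windows)
        if record_probs:
            probs[k] = p_exc[:: spec.n_exc_per_pathway]
        for idx in exc_spk.step(p_exc):
            exc_times[idx].append(t)
        for idx in inh_spk.step(p_inh):
            inh_times[idx].append(t)
    exc_trains = [SpikeTrain(i, np.asarray(ts)) for i, ts in enumerate(exc_times)]
    inh_trains = [SpikeTrain(i, np.asarray(ts)) for i, ts in enumerate(inh_times)]
    return exc_trains, inh_trains, probs


def _check_windows(windows: Sequence[LearningWindowSpec], T: float) -> None:
    spans = sorted((w.t_start, w.t_end) for w in windows)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError("learning windows overlap")
    if spans and spans[-1][1] > T:
        raise ValueError("learning window extends past the simulation span")


def apply_learning_window(p_exc: np.ndarray, p_inh: np.ndarray, t: float,
                          spec: PathwaySpec,
                          windows: Sequence[LearningWindowSpec]):
    """Override pathway probabilities inside learning windows.

    Inside a window, inhibitory afferents fire at constant background for
    the full duration; excitatory afferents fire at background during the
    initial phase and at alpha_mu * p_active (replacing, not adding to,
    background) during the final active phase.
    """
    for w in windows:
        if w.t_start <= t < w.t_end:
            p_inh = np.full_like(p_inh, spec.p_bg_inh)
            if t < w.t_start + w.background_ms:
                p_exc = np.full_like(p_exc, spec.p_bg_exc)
            else:
                p_exc = np.repeat(w.alpha_mu * w.p_active,
                                  spec.n_exc_per_pathway)
            break
    return p_exc, p_inh


def build_recall_pattern(spec: RecallStimulusSpec,
                         impact_order_E: np.ndarray,
                         impact_order_I: np.ndarray):
    """Per-neuron external spike probabilities for the recall phase.

    ``impact_order_E``/``impact_order_I`` are permutations of the
    excitatory/inhibitory network neurons ordered from most to least
    impactful.  In the ordered pattern the most impactful excitatory
    neuron receives pE_max (ramping linearly to 0 along the ranking)
    while inhibitory drive ramps the opposite way from 0 to pI_max.
    ``partial_shuffle`` redraws a ``shuffle_fraction`` subset uniformly
    in [0, pE_max] / [0, pI_rand_max]; ``random`` redraws everyone.
    Returns ``(pE, pI)`` indexed by neuron id.
    """
    impact_order_E = np.asarray(impact_order_E)
    impact_order_I = np.asarray(impact_order_I)
    nE, nI = impact_order_E.size, impact_order_I.size
    for order, n in ((impact_order_E, nE), (impact_order_I, nI)):
        if not np.array_equal(np.sort(order), np.arange(n)):
            raise ValueError("impact order must be a permutation of 0..n-1")
    rank_E = np.empty(nE)
    rank_E[impact_order_E] = np.arange(nE)
    rank_I = np.empty(nI)
    rank_I[impact_order_I] = np.arange(nI)
    pE = spec.pE_max * (1.0 - rank_E / max(nE - 1, 1))
    pI = spec.pI_max * (rank_I / max(nI - 1, 1))
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "random":
        pE = rng.uniform(0.0, spec.pE_max, nE)
        pI = rng.uniform(0.0, spec.pI_rand_max, nI)
    elif spec.kind == "partial_shuffle" and spec.shuffle_fraction > 0:
        mE = rng.random(nE) < spec.shuffle_fraction
        mI = rng.random(nI) < spec.shuffle_fraction
        pE[mE] = rng.uniform(0.0, spec.pE_max, mE.sum())
        pI[mI] = rng.uniform(0.0, spec.pI_rand_max, mI.sum())
    return pE, pI


def spike_trains_to_frame(trains):
    """Tidy (source_id, time_ms) table from a list of spike trains."""
    import pandas as pd

    ids = np.concatenate([np.full(t.times.size, t.source_id, dtype=int)
                          for t in trains]) if trains else np.empty(0, int)
    times = np.concatenate([t.times for t in trains]) if trains else np.empty(0)
    return pd.DataFrame({"source_id": ids, "time_ms": times})
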