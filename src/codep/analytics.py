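"""Closed-form theory and summary statistics for co-dependent plasticity.

The fixed-point expressions assume stationary presynaptic rates, weak
pre/post spike correlations in the heterosynaptic and LTD terms, and a
threshold-linear postsynaptic rate model

    nu_post = nu* * (X / E* - 1) + <nu_I><w_I> / w_I*

where X is the summed filtered NMDA current (mV), E* the rheobase
current and nu*/E* the current-to-rate gain.  The parameters nu*, E*
and w_I* depend on the neuron model and are calibrated from simulated
rate-current curves (:func:`fit_rate_model`).

Unit conventions: rates in Hz, time constants in ms; products of the two
are converted internally (nu[1/ms] = nu[Hz] / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .plasticity import ESPParams, ISPParams, inhibitory_gate

__all__ = [
    "RateModelParams",
    "ReadoutModel",
    "steady_state_total_E",
    "het_vanish_threshold",
    "recurrent_max_E",
    "pairwise_dw_E",
    "pairwise_dw_I",
    "clustering_index",
    "smoothed_rate_deviation",
    "response_norm",
    "train_readout",
    "fit_rate_model",
    "grid_sweep",
]

_KHZ = 1e-3  # Hz -> 1/ms


@dataclass
class RateModelParams:
    """Threshold-linear rate model of the postsynaptic neuron."""

    nu_star: float = 10.0       # rate gain (Hz)
    E_star: float = 50.0        # rheobase total NMDA current (mV)
    w_I_star: float = 1.0       # inhibitory scale
    mean_nu_I: float = 0.0      # mean inhibitory afferent rate (Hz)
    mean_w_I: float = 0.0       # mean inhibitory weight
    mean_nu_pre: float = 10.0   # mean presynaptic excitatory rate (Hz)

    def __post_init__(self) -> None:
        if min(self.nu_star, self.E_star, self.w_I_star) <= 0:
            raise ValueError("nu_star, E_star and w_I_star must be > 0")


def steady_state_total_E(esp: ESPParams, rm: RateModelParams) -> float:
    """Fixed point of the summed filtered NMDA current without LTD (mV).

    Balance of the potentiation (linear in the current) and
    heterosynaptic (quadratic) terms, with the postsynaptic rate
    eliminated through the rate model:

        X = B + sqrt(B^2 + A_LTP <nu_j> tau+ E* / (A_het tau_ypost nu*)),
        B = (E*/2) (1 - <nu_I><w_I> / (nu* w_I*)).

    With LTD present this is an upper bound on the total current.
    """
    if esp.A_het <= 0:
        raise ValueError("A_het must be > 0")
    B = 0.5 * rm.E_star * (
        1.0 - rm.mean_nu_I * rm.mean_w_I / (rm.nu_star * rm.w_I_star)
    )
    D = (esp.A_LTP * (rm.mean_nu_pre * _KHZ) * esp.tau_plus * rm.E_star
         / (esp.A_het * esp.tau_ypost * (rm.nu_star * _KHZ)))
    return B + float(np.sqrt(B * B + D))


def het_vanish_threshold(esp: ESPParams, rm: RateModelParams) -> float:
    """Heterosynaptic learning rate above which synapses may vanish.

    Derived for low postsynaptic rates assuming two consecutive
    postsynaptic spikes (heterosynaptic trace at 1 rather than its mean):

        A_het = A_LTP nu* <nu_j> tau+ tau_ypost
                / (E* [1 + tau_ypost (nu* - <nu_I><w_I>/w_I*)])
    """
    nu_star = rm.nu_star * _KHZ
    nu_pre = rm.mean_nu_pre * _KHZ
    nu_inh = rm.mean_nu_I * _KHZ
    denom_inner = 1.0 + esp.tau_ypost * (
        nu_star - nu_inh * rm.mean_w_I / rm.w_I_star
    )
    if denom_inner <= 0:
        raise ValueError("invalid regime: denominator term is nonpositive")
    return (esp.A_LTP * nu_star * nu_pre * esp.tau_plus * esp.tau_ypost
            / (rm.E_star * denom_inner))


def recurrent_max_E(esp: ESPParams) -> float:
    """Maximum filtered NMDA current onto a recurrently embedded neuron.

    With nu_j = nu_post the rates cancel:  A_LTP tau+ / (A_het tau_ypost).
    """
    if esp.A_het <= 0:
        raise ValueError("A_het must be > 0")
    return esp.A_LTP * esp.tau_plus / (esp.A_het * esp.tau_ypost)


def pairwise_dw_E(dt_LTP: float, dt_het: float, dt_LTD: float,
                  E: float, I: float, w0: float, esp: ESPParams) -> float:
    """Closed-form excitatory weight change for an isolated spike pattern.

    dt_LTP: pre-before-post lag; dt_het: interval between two consecutive
    postsynaptic spikes; dt_LTD: post-before-pre lag (all >= 0, ms), with
    frozen neighborhood traces E and I.
    """
    if min(dt_LTP, dt_het, dt_LTD) < 0:
        raise ValueError("lags must be nonnegative")
    if E < 0 or I < 0:
        raise ValueError("E and I must be nonnegative")
    bracket = (esp.A_LTP * np.exp(-dt_LTP / esp.tau_plus) * E
               - esp.A_het * np.exp(-dt_het / esp.tau_ypost) * E ** 2
               - esp.A_LTD * np.exp(-dt_LTD / esp.tau_minus) * w0)
    return float(bracket * inhibitory_gate(I, esp.I_star, esp.gamma, esp.I_th))


def pairwise_dw_I(dt: float, E: float, I: float, isp: ISPParams) -> float:
    """Closed-form inhibitory weight change for an isolated spike pair.

    Symmetric in the sign of the lag:  A_ISP E (E - alpha I) e^{-|dt|/tau}.
    """
    if E < 0 or I < 0:
        raise ValueError("E and I must be nonnegative")
    return float(isp.A_ISP * E * (E - isp.alpha * I)
                 * np.exp(-abs(dt) / isp.tau_iSTDP))


def clustering_index(w_coactive, w_independent) -> float:
    """Normalized contrast between co-active and independent mean weights.

    (<w_co> - <w_ind>) / (<w_co> + <w_ind>) in [-1, 1]; 1 when only
    co-active synapses survive, -1 when only independent ones do, and 0
    (by definition) when both means vanish.
    """
    w_co = np.asarray(w_coactive, dtype=float)
    w_ind = np.asarray(w_independent, dtype=float)
    if w_co.size == 0 or w_ind.size == 0:
        raise ValueError("weight sets must be nonempty")
    if np.any(w_co < 0) or np.any(w_ind < 0):
        raise ValueError("weights must be nonnegative")
    a, b = w_co.mean(), w_ind.mean()
    if a + b == 0.0:
        return 0.0
    return float((a - b) / (a + b))


def smoothed_rate_deviation(spikes, baseline_rates, T: float,
                            Delta_T: float = 20.0, sigma_r: float = 10.0,
                            n_half: int = 50) -> np.ndarray:
    """Trial-averaged, Gaussian-smoothed normalized rate deviations.

    ``spikes``: list over trials of lists over neurons of spike-time
    arrays (ms), or a single trial's list of arrays.  Counts are binned
    at ``Delta_T`` over [0, T), converted to rates, normalized as
    (rate - baseline)/baseline per neuron, then smoothed with a
    normalized Gaussian window (s.d. ``sigma_r`` ms, +-``n_half`` bins).
    Returns an (n_neurons, n_bins) array.
    """
    baseline = np.asarray(baseline_rates, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline rates must be > 0")
    if spikes and isinstance(spikes[0], np.ndarray):
        spikes = [spikes]
    n_neurons = baseline.size
    edges = np.arange(0.0, T + Delta_T, Delta_T)
    n_bins = edges.size - 1
    counts = np.zeros((n_neurons, n_bins))
    for trial in spikes:
        if len(trial) != n_neurons:
            raise ValueError("neuron count mismatch between trials")
        for j, times in enumerate(trial):
            counts[j] += np.histogram(times, bins=edges)[0]
    rates = counts / len(spikes) / (Delta_T * 1e-3)  # Hz
    dev = (rates - baseline[:, None]) / baseline[:, None]
    k = np.arange(-n_half, n_half + 1) * Delta_T
    win = np.exp(-k ** 2 / (2.0 * sigma_r ** 2))
    win /= win.sum()
    smoothed = np.empty_like(dev)
    for j in range(n_neurons):
        smoothed[j] = np.convolve(np.pad(dev[j], n_half, mode="edge"),
                                  win, mode="valid")
    return smoothed


def response_norm(deviation_series: np.ndarray) -> float:
    """l2 norm of rate deviations over neurons and time bins."""
    d = np.asarray(deviation_series, dtype=float)
    return float(np.sqrt(np.sum(d * d)))


@dataclass
class ReadoutModel:
    """Linear two-channel readout of population rate deviations."""

    a: np.ndarray
    b: np.ndarray
    x0: float
    y0: float
    sigma_r: float = 10.0
    Delta_T: float = 20.0
    noise_amplitude: float = 0.02

    def predict(self, rates: np.ndarray,
                rng: Optional[np.random.Generator] = None):
        """Readout coordinates for an (n_bins, n_neurons) rate array.

        With ``rng`` given, uniform noise in +-noise_amplitude is added
        per bin (emulating a noisy motor output); otherwise noiseless.
        """
        x = rates @ self.a + self.x0
        y = rates @ self.b + self.y0
        if rng is not None:
            x = x + rng.uniform(-self.noise_amplitude, self.noise_amplitude,
                                x.shape)
            y = y + rng.uniform(-self.noise_amplitude, self.noise_amplitude,
                                y.shape)
        return x, y


def train_readout(rates_per_condition, targets, rcond: float = None
                  ) -> ReadoutModel:
    """Least-squares fit of the linear readout over all conditions.

    ``rates_per_condition``: list of (n_bins, n_neurons) arrays;
    ``targets``: list of (n_bins, 2) arrays of (x, y) coordinates in
    (-1, 1).  Minimizes the summed squared error in both coordinates;
    rank deficiency resolves to the minimum-norm solution.
    """
    R = np.vstack(list(rates_per_condition))
    T = np.vstack(list(targets))
    if T.shape[1] != 2:
        raise ValueError("targets must have two columns (x, y)")
    if np.any(T <= -1) or np.any(T >= 1):
        raise ValueError("target coordinates must lie in (-1, 1)")
    X = np.hstack([R, np.ones((R.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(X, T, rcond=rcond)
    return ReadoutModel(a=coef[:-1, 0].copy(), b=coef[:-1, 1].copy(),
                        x0=float(coef[-1, 0]), y0=float(coef[-1, 1]))


def fit_rate_model(total_E: np.ndarray, nu_post: np.ndarray,
                   mean_nu_pre: float,
                   inhibitory_drive: Optional[np.ndarray] = None
                   ) -> RateModelParams:
    """Calibrate the threshold-linear rate model from simulation data.

    Fits nu_post ~ g * X - c (suprathreshold points only) and maps to
    nu* = c * g / (g) ... explicitly: gain g = nu*/E* and intercept
    c = nu*, so nu* = c and E* = c / g.  When ``inhibitory_drive``
    (= nu_I * w_I per run) is provided a third regressor estimates
    1/w_I_star.
    """
    X = np.asarray(total_E, dtype=float)
    nu = np.asarray(nu_post, dtype=float)
    mask = nu > 0
    if mask.sum() < 2:
        raise ValueError("need at least two suprathreshold observations")
    cols = [X[mask], -np.ones(mask.sum())]
    if inhibitory_drive is not None:
        cols.append(np.asarray(inhibitory_drive, dtype=float)[mask])
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, nu[mask], rcond=None)
    g, c = float(coef[0]), float(coef[1])
    if g <= 0 or c <= 0:
        raise ValueError("rate model fit produced nonpositive gain/rheobase")
    w_I_star = 1.0
    mean_nu_I = mean_w_I = 0.0
    if inhibitory_drive is not None and coef[2] != 0:
        w_I_star = abs(1.0 / float(coef[2]))
    return RateModelParams(nu_star=c, E_star=c / g, w_I_star=w_I_star,
                           mean_nu_I=mean_nu_I, mean_w_I=mean_w_I,
                           mean_nu_pre=mean_nu_pre)


def grid_sweep(func, grids: dict):
    """Brute-force sweep of ``func`` over the Cartesian product of grids.

    Returns a pandas DataFrame with one row per parameter combination
    and a ``value`` column.  Generic harness for parameter fitting.
    """
    import itertools

    import pandas as pd

    keys = list(grids)
    rows = []
    for combo in itertools.product(*(grids[k] for k in keys)):
        params = dict(zip(keys, combo))
        rows.append({**params, "value": func(**params)})
    return pd.DataFrame(rows)
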