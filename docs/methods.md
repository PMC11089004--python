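# Methods

`codep` simulates spiking neurons whose excitatory and inhibitory
synapses change according to *co-dependent* plasticity rules: the update
of one synapse depends on the recent synaptic currents of its neighbors,
not only on its own pre/post spike timing. This note documents the
model equations as implemented, the numerical scheme, the default
parameters and where they come from, and what the desk-scale study
conditions can and cannot show.

## Neuron models

**Point neuron.** A conductance-based leaky integrate-and-fire neuron
(voltages in mV, times in ms, conductances dimensionless relative to
leak):

    tau_m du/dt = -(u - u_rest) - g_AHP (u - E_AHP) + R I_ext
                  - g_AMPA (u - E_AMPA) - g_GABA (u - E_GABA)
                  - g_NMDA H(u) (u - E_NMDA)

Each synaptic conductance decays exponentially with its own time
constant and jumps by the synaptic weight at presynaptic spikes;
excitatory events increment both the AMPA and the per-synapse NMDA
conductance. The NMDA magnesium block

    H(u) = 1 / (1 + a exp(b (u - E_NMDA))),   a = 0.28, b = -0.062/mV

releases current with depolarization (b < 0); the constants follow the
classic voltage-dependence measurements at physiological Mg2+. Spiking
uses either a fixed threshold (spike, reset, clamp at `u_reset` for
`tau_ref`; used for all single-neuron work) or an adaptive threshold
(reset without clamping; the threshold jumps to `u_th_star` and decays
back to `u_th_0` with `tau_th`; used in the recurrent network). Because
the membrane potential cannot exceed E_NMDA, the adaptive threshold
implies an absolute refractory period

    tau_ref = tau_th ln[(u_th_star - u_th_0) / (E_NMDA - u_th_0)],

exposed as `adaptive_refractory`. After-hyperpolarization: `g_AHP`
jumps by `A_AHP` at each spike and decays with `tau_AHP`; it is the main
rate brake in the recurrent network. The AHP conductance keeps decaying
during the fixed refractory period (the clamp applies to the membrane
potential only).

**Two-layer neuron.** A spiking soma coupled to passive dendritic
branches. Synapses target branches; branch i couples to the soma with
conductance J_i, related to electrotonic distance by J = (d*/d)^2 and to
steady-state attenuation by a = J/(1+J). Branches have no threshold, so
the Mg-block nonlinearity produces NMDA plateau potentials that can
exceed the somatic threshold.

## Plasticity rules

Every postsynaptic compartment carries current-derived traces:

* `Etilde_j` — per-synapse low-pass filter (time constant `tau_E`) of
  the synapse's NMDA current magnitude, in mV,
* `E_j` — distance-weighted sum of the `Etilde_k` of neighboring
  synapses (see kernel below),
* `I` — low-pass filter (`tau_I`) of the compartment's total GABA_A
  current, in mV,

plus the usual exponentially decaying spike traces (`x+_j`, `y_E`,
`y-`, and the symmetric pair `x_j`, `y_post`).

**Excitatory rule.** At each postsynaptic spike every excitatory
synapse j changes by

    dw_j = gate(I) [ A_LTP x+_j E_j  -  A_het y_E E_j^2 ],

and at each presynaptic spike on j by

    dw_j = -gate(I) A_LTD y- w_j,

with gate(I) = exp[-(I/I*)^gamma] for I <= I_th and exactly 0 above
I_th (hard block; by default I_th is placed where the smooth gate
reaches 1e-3, so the cutoff is numerically seamless). The linear-in-E
potentiation and quadratic-in-E heterosynaptic weakening create a
stable setpoint for the total excitatory current; inhibition gates the
whole rule, so weights reorganize only during disinhibition. Weights
are hard-clipped to [1e-5, 10].

**Inhibitory rule.** A symmetric STDP window scaled by the co-dependency
factor:

    dw_k = A_ISP E (E - alpha I) x_k        at postsynaptic spikes,
    dw_k = A_ISP E (E - alpha I) y_post     at presynaptic spikes on k,

where E is the compartment-wide sum of the filtered NMDA currents. The
rule's fixed point is the current balance E = alpha I; no change occurs
when excitation vanishes. Weights are clipped to [1e-5, 70].

**Distance kernel.** With 1-D synapse positions, the neighborhood trace
is E_i = sum_j F[i,j] Etilde_j with

    F[i,j] = exp(-dx_ij^2 / 2 sigma^2) /
             [(1/N) sum_k exp(-dx_ik^2 / 2 sigma^2)].

The mean-mass normalization makes sum_i E_i approximately N sum_j
Etilde_j independent of sigma (exact for sigma = inf, within 2% for
sigma >= 1 at N = 100 equally spaced synapses; edge effects account for
the deviation). sigma = inf short-circuits to the all-to-all sum, which
is also what the inhibitory rule and all single-compartment experiments
without explicit positions use.

## Numerical scheme

Forward Euler for the membrane potential at dt = 0.1 ms (configurable).
All linear first-order decays — conductances, AHP, adaptive threshold,
spike traces — use the exact per-step factor exp(-dt/tau); the current
traces relax exponentially toward their instantaneous source term.
Exact spike-trace decay is what lets isolated spike pairs reproduce the
closed-form pairwise weight changes to machine precision (the
acceptance suite checks 1e-10).

Per-step order: (1) decay conductances and traces, (2) presynaptic
conductance jumps, (3) membrane update and threshold test, (4)
plasticity updates, (5) spike-trace increments and current-trace
relaxation. Plasticity therefore reads spike traces *excluding* the
triggering spike's own increment (no self-pairing; simultaneous pre and
post events apply the potentiation branch before the depression branch)
and current traces lagged by one step. After the Euler step the
membrane potential is clamped to the hull of the reversal potentials
[min(E_GABA, E_AHP, u_reset), max(E_NMDA, E_AMPA)]; the exact solution
lives in that interval, and the clamp keeps forward Euler stable during
transient high-conductance episodes in the recurrent network.

"Enforced" postsynaptic plasticity events (default 1 Hz Poisson in the
feedforward stability protocol) enter the plasticity rule only — they
do not touch the membrane — and keep the rule sampling when output
spiking is weak.

## Rate model and closed-form theory

The fixed-point expressions in `codep.analytics` use a threshold-linear
rate model of the postsynaptic neuron,

    nu_post = nu* (X/E* - 1) + <nu_I><w_I>/w_I*,

where X is the summed filtered NMDA current: E* acts as a rheobase
current and nu*/E* as the gain. `fit_rate_model` calibrates nu* and E*
from static-weight simulations (X vs firing rate, suprathreshold points
only). With this relation, setting the potentiation/heterosynaptic
balance to zero with A_LTD = 0 gives the total-current setpoint

    X_ss = B + sqrt(B^2 + A_LTP <nu_pre> tau+ E* / (A_het tau_y nu*)),
    B = (E*/2)(1 - <nu_I><w_I>/(nu* w_I*)),

which reduces to exactly E* when A_LTP = 0 and there is no inhibition,
and is an upper bound when LTD is active. For a neuron embedded in a
recurrent network (nu_pre = nu_post) the maximum total current is
rate-independent:

    X_max = A_LTP tau+ / (A_het tau_y).

The derivation assumes stationary rates, weak pre/post correlations and
small trace fluctuations. Three regimes measurably violate it, and the
package documents rather than hides them:

* *Weight concentration.* With all-to-all interactions and no LTD, the
  heterosynaptic competition slowly concentrates weight onto a few
  synapses; the growing single-synapse EPSPs correlate pre and post
  spikes and pull the current fixed point below the prediction. The
  setpoint validation therefore measures over a defined window after
  convergence (15-55 s under the default desk conditions) while the
  weight distribution is still broad.
* *Spike-train structure.* The heterosynaptic trace sampled at
  postsynaptic spikes differs from its Poisson mean when firing is
  regular or bursty; slow traces (tau_y = 200 ms, tau_E >= 200 ms in
  the study configurations) keep the relative bias small.
* *Spike-time sampling of the balance.* The inhibitory rule's fixed
  point E = alpha I holds for the trace values sampled at spike times.
  In a feedforward neuron with independent afferents the time-averaged
  ratio lands within a few percent of alpha (with tau_I = 100 ms); in
  the recurrent network, spikes preferentially sample disinhibited
  moments and the time-averaged ratio sits well below alpha. The
  recurrent-network checks therefore test the connectivity structure
  (correlation signs, current bound, self-sustained dynamics), not the
  time-averaged ratio.

## Synthetic inputs

Afferents are refractory Bernoulli processes: in each step a source
fires with probability p unless it spiked within the preceding tau_ref
(5 ms excitatory, 2.5 ms inhibitory throughout). The closed-form mean
rate

    nu = (1/dt) p (1-p)^(tau_ref/dt)

is exposed as `rate_from_prob` (at p = 0.002, dt = 0.1 ms, tau_ref =
5 ms: 18.1 Hz). The literal generation rule has stationary rate
p / (dt (1 + p tau_ref/dt)); at the probabilities used here the two
differ by < 0.5%, well inside sampling error of any run we perform.
Constant-rate trains are sampled exactly via geometric inter-spike
intervals.

Pathway inputs share a rectified Ornstein-Uhlenbeck rate per pathway:
dy/dt = -y/tau_OU + xi(t), integrated by Euler-Maruyama with increment
xi sqrt(dt) and unit diffusion (the continuous-time scaling of the
noise is an interpretation; the amplitude p* = 0.025 is a free
multiplier, so the construction is unchanged up to that constant), and
p_j(t) = p* max(y_mu, 0) + p_bg. Learning windows (700 ms: 500 ms
background, 200 ms active at alpha_mu * p_active with p_active = 0.005)
clamp inhibitory afferents to constant background — the disinhibition
that opens the excitatory gate. Recall patterns map neuron impact
rankings to external spike probabilities by linear interpolation in
rank (pE: 0.5 -> 0, pI: 0 -> 0.25), with optional uniform reshuffling
of a subset (pE in [0, 0.5], pI in [0, 0.4]).

## Default parameters

Membrane and synaptic constants (tau_m = 20 ms, u_rest = -70 mV,
u_reset = -60 mV, u_th = -50 mV, E_AMPA = E_NMDA = 0 mV, E_GABA =
-80 mV, E_AHP = -90 mV, tau_AMPA = 5 ms, tau_NMDA = 50 ms, tau_GABA =
10 ms) are conventional cortical-model values and are package choices,
as are all learning rates and trace time constants — none of them claim
to reproduce any particular published parameter set. Reference values
adopted verbatim: the weight bounds (w_max^E = 10, w_max^I = 70,
w_min = 1e-5), the Mg-block constants, the pathway input statistics
(p* = 0.025, backgrounds 2e-4 / 4e-4), and the protocol constants (pair
counts, lags, durations, alpha_mu vectors). Defaults are exposed in the flat
YAML config schema (`codep validate --schema`), and every run manifest
records which keys were user-supplied versus defaulted.

Parameter sensitivity worth knowing about: the ratio A_LTP/A_het sets
every current setpoint; the absolute scale of the learning rates only
sets the convergence speed, but per-event weight jumps must stay small
relative to typical weights or the hard bounds rectify the updates and
shift the fixed points (the desk-scale defaults keep jumps below ~15%
of the operating weights). I* must be matched to the operating scale of
the I trace in each preparation: far below it the gate blocks all
excitatory plasticity, far above it inhibition loses control.

## Desk-scale study conditions

The full-scale recurrent network (1000 E / 250 I, a multi-hour learning
period under a three-stage decaying external drive) is configured but
long-running. The tested desk scale uses 200 E / 50 I neurons
(connection probability 0.2 per block, recurrent in-degree ~40), 100 s
of learning, and learning rates raised accordingly. Three desk-scale
adaptations matter and are deliberate:

* *Plasticity warm-up.* The rules are enabled only after a 10-s
  settling period; the startup transient would otherwise be read as an
  enormous excitatory current by the quadratic heterosynaptic term.
* *Constant moderate drive.* Learning runs under a constant per-step
  external probability of 0.002 rather than decaying to near zero. At
  this scale the near-silent network is only metastably active, and
  every stochastic re-ignition is a synchronized burst whose current
  transient destabilizes the weights; the constant drive keeps the
  network in a continuously active state while the rules organize the
  recurrent weights.
* *Burst-limited neurons.* A slow threshold decay (tau_th = 20 ms,
  implying a 6.7-ms effective refractory period) and a strong AHP
  (A_AHP = 0.5, tau_AHP = 100 ms) bound single-neuron instantaneous
  rates.

At 200 neurons the network's spiking remains strongly event-clustered
in every regime we probed, and the factorization assumption behind the
mean-field fixed points is measurably violated (the heterosynaptic
expectation sampled at postsynaptic spikes exceeds its factorized value
by roughly an order of magnitude at low rates). The recurrent-bound and
connectivity-correlation checks therefore carry substantially more
bias at desk scale than the feedforward checks, which do operate in
their theory's domain of validity. Recall probes at desk scale use a
weak keep-alive background drive (per-step probability 2e-4, identical
across stimulation patterns) because the learned self-sustained state
is fragile on some seeds; at full scale the recall phase runs with no
external input outside the stimulation window.

What the desk-scale tests show: heterosynaptic competition between
synapses switches on with the interaction length (the sigma transition),
the learned network amplifies impact-ordered stimulation more than
random stimulation, and receptive fields form, switch and persist.
What they cannot show: quantitative weight distributions, the
multi-hour consolidation dynamics that produce the full input/output
weight anticorrelation, or fits to experimental plasticity datasets
(out of scope by design).

## Known limitations

* Forward Euler with reversal clamping is first-order; halving dt
  changes single-neuron voltages by < 0.1% but can shift individual
  spike times in long chaotic network runs.
* The readout training uses closed-form least squares on smoothed,
  trial-averaged rate deviations; no benchmark of drawing quality is
  attempted.
* Synapse positions are 1-D with a Gaussian interaction kernel; no
  cable-equation dendrites beyond the two-layer scheme, no explicit
  action-potential waveform, no short-term or structural plasticity,
  and no plastic E->I / I->I blocks.
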