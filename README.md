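# codep — co-dependent excitatory/inhibitory synaptic plasticity

`codep` is a simulation package for studying synaptic plasticity rules
in which neighboring synapses regulate each other. It is aimed at
computational neuroscientists who want to reproduce and extend
single-neuron plasticity experiments (voltage-, frequency- and
distance-dependent STDP, receptive-field reshaping, dendritic
clustering) and to grow recurrent spiking networks whose connectivity
self-organizes into stable, input-sensitive structure.

## The model

Excitatory (E→E) and inhibitory (I→E) synapses change according to
rules of the form Δw = φ(E, I; PRE, POST), where E and I are low-pass
filters of the local NMDA and GABA_A currents (in mV, since
conductances are dimensionless) and PRE/POST are spike traces. For an
excitatory synapse j:

    dw_j/dt = { [ A_LTP x⁺_j(t) E_j(t) − A_het y^E(t) E_j(t)² ] S_post(t)
                − A_LTD y⁻(t) S_j(t) w_j(t) } · exp[−(I(t)/I*)^γ]

— spike-timing-dependent potentiation scaled linearly by neighboring
excitation, heterosynaptic weakening scaled quadratically (together
they form a setpoint for the total excitatory current), weight-
proportional depression, and a multiplicative inhibitory gate that
blocks all excitatory plasticity unless the synapse is disinhibited.
For an inhibitory synapse, a symmetric STDP window scaled by
A_ISP·E·(E − αI) pushes the local excitation/inhibition ratio toward
the setpoint α. Neighborhood is defined by a Gaussian kernel over
synapse positions (width σ), or all-to-all within a compartment.

The neurons are conductance-based leaky integrate-and-fire models with
AMPA/NMDA/GABA_A synapses, a voltage-dependent NMDA magnesium block,
an after-hyperpolarization current, and fixed or adaptive thresholds;
a two-layer variant adds passive dendritic branches whose coupling to
the soma encodes electrotonic distance. Closed-form theory for the
current setpoints, the heterosynaptic vanishing threshold, the
recurrent current bound and pairwise weight changes lives in
`codep.analytics`. See `docs/methods.md` for the full model account.

## Worked example

Pair a presynaptic and a postsynaptic spike ten milliseconds apart at a
synapse embedded in a quiet (disinhibited) neighborhood, and compare
the event-driven rule with the closed-form prediction:

```python
import numpy as np
from codep import NeuronParams, ESPParams
from codep.engine import FeedforwardSimulation, scheduled_drive
from codep.analytics import pairwise_dw_E

esp = ESPParams()                       # A_LTP=3e-3, tau_plus=17 ms, ...
sim = FeedforwardSimulation(
    NeuronParams(u_th=1e6),             # membrane spiking disabled
    w_exc=[1.0], w_inh=[],
    exc_drive=scheduled_drive([np.array([50.0])], dt=0.1),
    esp=esp, scheduled_post=np.array([60.0]), dt=0.1)
sim.traces.update_currents = lambda *a, **k: None   # freeze E and I
sim.traces.E = np.array([5.0]);  sim.traces.I = 0.3
sim.run(200.0)

print(f"simulated dw = {sim.w_exc[0] - 1.0:.10f}")
print(f"closed form  = {pairwise_dw_E(10.0, np.inf, np.inf, 5.0, 0.3, 1.0, esp):.10f}")
```

Output:

    simulated dw = 0.0076126772
    closed form  = 0.0076126772

The weight grows by A_LTP·e^(−10/17)·E·gate ≈ 0.0076: pre-before-post
pairing at low inhibition potentiates, and the event-driven simulation
reproduces the analytic pairwise change to machine precision. The
generator-side closed form is equally direct:

```python
from codep import rate_from_prob
rate_from_prob(0.002, 0.1, 5.0)   # -> 18.09 Hz mean afferent rate
```

Experiment protocols are one call each (`codep.protocols.run_voltage_stdp`,
`run_frequency_stdp`, `run_distance_stdp`, `run_feedforward_stability`,
`run_receptive_field`, `run_dendritic_clustering`), or from the shell:

    codep run receptive-field --seed 3 --out results/rf
    codep theory bound --config my.yaml
    codep validate

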