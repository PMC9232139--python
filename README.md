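# entsim

Conductance-based simulation of enteric S-neurons (myenteric interneurons and
motor neurons) and of how their four kinds of depolarizing synaptic input
interact: fast EPSPs, slow EPSPs (metabotropic slow synaptic
depolarizations), and ionotropic GABA_A / GABA_C chloride synapses.

The scientific question the package addresses: slow EPSPs depolarize enteric
neurons for tens of seconds — do they make fast-EPSP-evoked firing more or
less likely?  The model shows a biphasic answer: during the sustained phase
of a slow depolarization, voltage-dependent accommodation (M-current
activation, sodium-channel inactivation) and chloride shunting suppress
firing even though the membrane sits closer to threshold.  The same circuit
motifs show that GABA_A input sums with fast EPSPs to promote firing, while
the slow GABA_C conductance is excitatory at first and shunting later.

Intended users: computational neuroscientists and enteric-neurophysiology
groups who want a dependency-light, scriptable re-implementation of this
class of model (no NEURON installation required).

## The model

Single neuron: a 10-segment cylindrical soma (diameter 25 um, length 49 um,
Cm = 1 uF/cm^2) with Hodgkin–Huxley channels

    I_NaV1.3 = g m1^3 m2 m3 (v - E_Na)     fast Na+, with slow inactivation
    I_NaV1.7 = g m1^3 m2 m3 (v - E_Na)     small Na+ current
    I_Kdr    = g m (v - E_K)               delayed rectifier
    I_KA     = g m1^3 m2 (v - E_K)         A-type K+
    I_Kv7.2  = g m1^3 m2 (v - E_K)         M-current (phasic firing)

plus a passive leak solved so the cell rests at -55 mV.  All rate laws and
the constants resolving typographic ambiguities ship in
`src/entsim/data/channels.yaml`.

Synapses: biexponential conductances g(t) ∝ exp(-t/τ2) − exp(-t/τ1),
peak-normalised so `weight` is the single-event peak conductance in uS
(fast EPSP τ = 1/5 ms, E = 0 mV; GABA_A τ = 0.285/5.6 ms and GABA_C
τ = 20/50 ms, both with E_Cl = -35 mV).  The slow EPSP is a second-messenger
cascade (units 1/s)

    dD/dt = α1 I(t) − β1 D        (cAMP)
    dC/dt = α2 D^2  − β2 C        (PKA catalytic subunit)
    dP/dt = −α3 C P + β3 (1 − P)  (unphosphorylated K channel fraction)

whose product g_sK · P is a standing potassium conductance; phosphorylation
(P < 1) closes it and depolarizes the neuron for ~10 s or more.

Networks: spike generators drive input neurons one-to-one; input neurons
converge on a recording neuron through one synapse type each.  Synaptic
weights are calibrated by bisection to the single-event spike threshold and
set to 0.95× ("subthreshold") or 1.05× ("suprathreshold") of it, as in the
modelled experiments.

## Worked example

Run the synchronous subthreshold fast-EPSP + GABA_A protocol (one generator,
5-pulse burst at 20 ms intervals, weights calibrated to 0.95× threshold):

```bash
$ entsim run fig3_gabaa_fepsp --seed 1
        protocol  seed  input_spikes  output_spikes  first_amplitude_mv  last_amplitude_mv  amplitude_drop_mv
fig3_gabaa_fepsp     1             5              5            8.629845           0.958953           7.670892
```

Each of the 5 input-neuron spikes evokes an output action potential: two
individually subthreshold inputs sum to fire the recording neuron on every
pulse.  The first spike peaks at +8.6 mV; the last, riding accumulated
accommodation, at +1.0 mV.

The same from Python:

```python
import entsim
r = entsim.run_protocol("fig3_gabaa_fepsp", seed=1)
print(r.output_spike_count)        # 5
print(r.input_spike_counts)        # {'gen': 5}
```

`entsim list` names all protocols (current-step validation, slow-EPSP
rising/sustained interactions, GABA_A/GABA_C combinations);
`entsim calibrate fig4b` prints calibrated weights;
`entsim run <protocol> --out DIR` writes a reproducible bundle (traces.csv,
events.jsonl, summary.json, resolved config, manifest with checksums).

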