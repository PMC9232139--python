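# Methods

## Scope and model structure

The package simulates enteric S-neurons (interneurons and motor neurons of
the gut wall) as single-compartment-like somata — ten short cylindrical
segments, diameter 25 um, length 49 um, Cm = 1 uF/cm^2, axial resistivity
100 Ω·cm — with five Hodgkin–Huxley channels (NaV1.3, NaV1.7, delayed
rectifier, A-type K, Kv7.2), a passive leak, and event-driven synapses.
With this geometry the soma is quasi-isopotential (inter-segment spread
< 1 mV during an action potential; asserted in the test suite), so the
segmentation reproduces the source morphology without adding electrotonic
structure.

Four synaptic mechanisms are modelled.  Fast EPSP, GABA_A and GABA_C are
biexponential conductances; the slow EPSP is a cAMP → PKA →
channel-phosphorylation cascade that closes a standing potassium
conductance g_sK·P.  Networks are feed-forward motifs: spike generators →
input neurons (driven 1:1 through a strong fast synapse) → one recording
neuron.

## Parameters, units and defaults

Channel densities are in S/cm^2, potentials in mV, synaptic conductances in
uS, currents in nA, time in ms (the cascade in s — see below).  Table
defaults: g_NaV1.3 = g_NaV1.7 = g_Kdr = 0.01, g_KA = 0.0014 S/cm^2,
E_Na = 55, E_K = −85, E_Cl = −35 mV; fast EPSP τ = 1/5 ms; GABA_A
τ = 0.285/5.6 ms; GABA_C τ = 20/50 ms; cascade rates α1 = α2 = α3 = 0.22,
β1 = 0.41, β2 = 0.27, β3 = 0.12 s⁻¹.

Several constants in the source rate laws are typeset so that they cannot be
parsed uniquely; they are resolved in `data/channels.yaml` (the file
documents each choice) rather than in code:

* **NaV1.3 m1 β and fast-inactivation rates** — trap forms with removable
  singularities; the literal alternative parses have poles.
* **NaV1.7 m2 β, m3 β** — the recognisable sigmoidal rate set, with the m3
  equations (mislabelled m2 in the source) assigned to the slow gate.
* **Kdr time constant** — 0.27 + 5.1/(1+exp(−(v+27)/15.6)) ms: a delayed
  rectifier, slow to activate at spike voltages (~4–5 ms), fast to
  deactivate below rest (~1 ms).  The printed digit string admits several
  sub-millisecond parses, all of which clamp the action potential entirely.
* **Kv7.2** — half-activation −49.8 mV (the printed "49.8" with no sign; at
  +49.8 the channel never opens in the physiological range and cannot
  convert tonic to phasic firing), g = 1e−3 S/cm^2.  The tabulated
  0.15 S/cm^2 would exceed the leak conductance ~100-fold at rest.  The
  value used was calibrated once against the stated validation behaviour:
  with the channel, a suprathreshold 500 ms step fires only at onset;
  without it, firing spans the step.
* **M (maximum escape from Na slow inactivation)** — no tabulated value;
  default 0.6.  Below ~0.5 the sodium current available at a −55 mV rest
  cannot produce detectable spikes; above ~0.65 strong steps end in stable
  depolarized plateaus.
* **Temperature** — q = 2^((T−24)/10) multiplies the NaV1.3 activation and
  fast-inactivation rates; default T = 24 °C makes it inert.

Resting potential: −55 mV (E_Cl 20 mV positive to rest, inside the reported
15–25 mV window).  The leak reversal is solved per neuron so that total
steady current — channels at steady state, slow-K pool at P = 1 — vanishes
exactly at v_rest.  At −50 mV the printed inactivation midpoints (fast −50,
slow −58 mV) leave under 16 % of the sodium conductance available and the
neuron cannot fire at all; −55 mV is the least-hyperpolarized rest at which
all validation behaviours coexist.

Spike detector: upward crossings of −15 mV separated by ≥ 2 ms.  With
E_Cl = −35 mV, action potentials riding a strong chloride shunt are
truncated and peak between −20 and +10 mV; the source counts such truncated
events as spikes, and −15 mV detects them while staying safely above the
largest purely synaptic envelope (−35 mV for chloride synapses, ≈ −23 mV for
the strongest fast-EPSP weight in use).  The threshold is exposed in the run
configuration.

## Slow EPSP coupling and calibration

Each presynaptic spike contributes a rectangular agonist pulse (amplitude =
synaptic weight, duration 50 ms, pulses summing).  The cascade runs in
seconds — P recovers with 1/β3 ≈ 8.3 s, matching slow EPSP durations of tens
of seconds — and is advanced inside the membrane loop with exact/exponential
sub-steps (D exactly, C and P exponentially with frozen drivers), which
preserves D, C ≥ 0 and P ∈ [0, 1] unconditionally.

g_sK = 0.03 uS: a saturating 5-pulse train then sustains a ~15 mV
depolarization (the reported 10–20 mV range) without letting the standing
pool dominate the resting conductance.  Because no cascade-speed
depolarization can outrun the transcribed accommodation gates (see
Limitations), slow-EPSP weights are calibrated on the standard 5-pulse
train with a peak-voltage criterion: the threshold weight is the one whose
train peak reaches the regenerative takeoff voltage (−42 mV, the voltage at
which the default neuron's sodium upstroke begins under fast drive).
Sub/supra weights are 0.95×/1.05× threshold, as for all other synapses.

Conditioned protocols (test bursts delivered during a slow depolarization)
reuse the test-input weights calibrated in their unconditioned reference
networks, mirroring the cross-figure weight reuse of the modelled
experiments.

## Numerics

Backward Euler for the voltage (tridiagonal solve across segments), exact
exponential updates for gates at frozen voltage, with gate steady states and
time constants tabulated on a 0.05 mV grid and linearly interpolated inside
a compiled (numba) kernel; dt = 0.025 ms.  Divergence (|v| > 200 mV) raises
an error naming the failure time.  Spike counts of all network protocols
are invariant under dt halving (asserted); individual spike times within an
adapting burst drift by up to a few tenths of a millisecond between dt
levels because threshold-marginal later spikes amplify the O(dt) splitting
error, while the onset spike time converges below 0.05 ms.

Weight calibration bisects to 1 % relative bracket width, starting from a
doubling search; a missing bracket (no response at any weight up to the
cap) raises a calibration error reporting the search range.  Calibration is
deterministic, so results are cached per network signature within a
process.

Problem sizes: every protocol simulates ≤ 6.5 s of model time at
dt = 0.025 ms; a full acceptance recomputation (all calibrations plus eight
protocols) takes well under a minute on one CPU, and the stochastic-mode
checks in the test suite use 20 seeds per protocol.

## What the generators emulate

Bursts of 5 events with inter-spike intervals uniform in 20–30 ms, truncated
at 200 ms, reproduce the stimulation of the modelled experiments; the
deterministic mode (fixed 20 ms ISI, the stated 50 Hz burst) is used for the
headline counts to remove sampling variability, and a single master seed is
expanded into independent per-generator substreams.  The generators are
regular by construction: no synaptic noise, spontaneous release, jittered
delays or heterogeneous populations, so passing tests say nothing about
robustness to biological variability — the modelled experiments excluded
those elements deliberately.

## Known limitations and discrepancies

* **Rising-phase facilitation is absent.**  Under the transcribed gate
  kinetics every accommodation process (Na fast inactivation τ ≈ 5–17 ms,
  Na slow inactivation τ < 100 ms above −50 mV, Kv7.2 τ ≈ 11/93 ms)
  equilibrates faster than the second-messenger cascade can depolarize the
  membrane (~1 s at calibrated weights), so sodium availability falls in
  lockstep with the slow depolarization and subthreshold fast EPSPs are
  never facilitated during the rise, at any test onset.  The
  sustained-phase suppression — the central result — reproduces robustly.
  The corresponding test is left failing rather than re-tuned.
* **GABA_C spike counts undershoot.**  The chloride shunt at calibrated
  GABA_C weights, combined with the transcribed sodium inactivation,
  suppresses pulses 3–5 of the combined trains: the
  facilitation-then-suppression pattern and the ~19 mV amplitude reduction
  of later spikes reproduce, but the combined-train counts are 2 where the
  modelled behaviour reports 3 (GABA_A+GABA_C sub gives the reported 2) or
  5.  Likewise the recording neuron that carries the slow-EPSP conductance
  pool is ~2.3× stiffer than the unconditioned reference neuron, so
  transplanted just-subthreshold weights cannot fire it (single-conditioned
  count 0 instead of 5).
* Slow-EPSP inputs cannot fire the neuron at the onset of the depolarization
  (same accommodation argument), so "suprathreshold" slow EPSPs are defined
  by their peak voltage, not by onset firing.
* The Kv7.2 excitability relation inverts far above rheobase: without the
  M-current the neuron enters sodium-inactivation block under strong steps,
  so "removing Kv7.2 increases firing" holds near rheobase only.
* Dendrites/axons, stochastic gating, receptor desensitization and
  presynaptic or metabotropic modulation of ligand-gated channels are out of
  scope.
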