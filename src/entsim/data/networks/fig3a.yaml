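# Fast-EPSP + GABA_A convergence; both input neurons share one generator so
# their synaptic events reach the recording neuron synchronously.
name: fig3a
neuron: {}
generators:
  gen: {n_events: 5, start_time: 300.0}
connections:
- {name: fepsp_in, syn_type: fepsp, weight_mode: sub, generator: gen}
- {name: gabaa_in, syn_type: gabaa, weight_mode: sub, generator: gen}
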