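# GABA_A + GABA_C convergence, shared generator (equal conduction delays).
name: fig4a
neuron: {}
generators:
  gen: {n_events: 5, start_time: 300.0}
connections:
- {name: gabaa_in, syn_type: gabaa, weight_mode: sub, generator: gen}
- {name: gabac_in, syn_type: gabac, weight_mode: sub, generator: gen}
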