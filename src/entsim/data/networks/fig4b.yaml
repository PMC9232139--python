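# Fast-EPSP + GABA_C convergence, shared generator.
name: fig4b
neuron: {}
generators:
  gen: {n_events: 5, start_time: 300.0}
connections:
- {name: fepsp_in, syn_type: fepsp, weight_mode: sub, generator: gen}
- {name: gabac_in, syn_type: gabac, weight_mode: sub, generator: gen}
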