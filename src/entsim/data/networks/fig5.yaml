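# Small slow depolarization (single stimulus) conditioning synchronous
# fast-EPSP + GABA_C test inputs.
name: fig5
neuron: {}
generators:
  gen_slow: {n_events: 1, start_time: 300.0}
  gen_test: {n_events: 5, start_time: 3300.0}
connections:
- {name: sepsp_in, syn_type: sepsp, weight_mode: sub, generator: gen_slow}
- {name: fepsp_in, syn_type: fepsp, weight_mode: sub, generator: gen_test}
- {name: gabac_in, syn_type: gabac, weight_mode: sub, generator: gen_test}
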