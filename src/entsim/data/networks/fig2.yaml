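# Slow-EPSP + fast-EPSP convergence onto one recording neuron.
# gen_slow drives the slow-EPSP input neuron; gen_test drives the fast-EPSP
# input neuron (its onset is set per protocol: rising vs sustained phase).
name: fig2
neuron: {}
generators:
  gen_slow: {n_events: 5, start_time: 300.0}
  gen_test: {n_events: 5, start_time: 500.0}
connections:
- {name: sepsp_in, syn_type: sepsp, weight_mode: sub, generator: gen_slow}
- {name: fepsp_in, syn_type: fepsp, weight_mode: sub, generator: gen_test}
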