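# Frog neuromuscular junction, 4-state chain (lambda = 50)
name: frog4
n_states: 4
alpha: 0.3
beta: 15.0
rho: 1.0
n_total: 10000
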