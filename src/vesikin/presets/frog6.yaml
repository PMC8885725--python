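# Frog, 6-state chain
name: frog6
n_states: 6
alpha: 1.43
beta: 9.5
rho: 1.0
n_total: 10000
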