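# Frog, 5-state chain (extra docked-like state; tabulated beta = 13.0
# takes precedence over lambda * alpha = 13.02)
name: frog5
n_states: 5
alpha: 0.62
beta: 13.0
rho: 1.0
n_total: 10000
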