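# Cat neuromuscular junction, 4-state chain (alpha from the 1.61-s
# spontaneous interval constant; lambda = beta/alpha = 100)
name: cat4
n_states: 4
alpha: 0.62
beta: 62.0
rho: 1.0
n_total: 10000
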