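# vesikin

Stochastic kinetics of synaptic vesicle priming, fusion and recycling at
the neuromuscular junction.

## The problem

Neuromuscular transmitter release spans several regimes — spontaneous
miniature events at rest, calcium-evoked quantal release on an impulse,
facilitation on closely spaced impulses, and depression after intense
activity.  `vesikin` models all of them with one mechanism: every vesicle
carries a fusion complex that matures through a serial chain of states,

```
        α(+f)      α(+f)      α(+f)
    D  ⇌  pP  ⇌  P  →  F  →  D
        β₁         β₂         ρ
```

docked (D), preprimed (pP), primed (P), fused (F).  The forward
(maturation) transitions share one rate constant α and are all accelerated
by the impulse-evoked calcium transient; the backward transitions β᎐ = λ᎐·α
are calcium-independent and 50–100 times faster than α, which pins ~98% of
the pool in the docked state at rest; fusion (P → F) and recycling
(F → D, rate ρ) are unidirectional.  Calcium enters as an additive rate
increment `f(t) = I_e exp(−(t−t_s)/τ_e)` on every forward transition, so
the effective forward rate during a transient is `α_s = α + f(t)`.

A pool of N₀ = 10,000 identical vesicles is evolved with a statistically
exact stochastic simulation algorithm for the resulting time-inhomogeneous
Markov jump process (waiting times thinned against the monotone bound that
holds between pulse onsets).  Because every propensity is linear in the
state, the mean dynamics obey a linear ODE system *exactly*; the package
ships this mean-field companion and uses it both as the engine's
correctness oracle and as a deterministic calibrator for the transient
amplitude I_e, which published work leaves in arbitrary units.

Intended users: synaptic physiologists and modellers who want a
reproducible, seedable simulator of quantal release statistics and
short-term plasticity from configuration alone.

## Worked example

Calibrate the calcium transient so one impulse releases 3% of the pool,
then run the classical conditioning-train protocol (three pulses 30 ms
apart, test pulse 250 ms later) on the frog parameter set:

```python
from vesikin.config import load_preset
from vesikin.protocols import calibrate_amplitude, run_train_test

spec = load_preset("frog4")            # α=0.3, β=15, ρ=1 s⁻¹, N₀=10,000
scheme = spec.scheme()
cal = calibrate_amplitude(scheme, spec.n_total, tau_e=1.3e-3,
                          target_fraction=0.03)
res = run_train_test(scheme, spec.n_total, seed=11, n_runs=100,
                     I_e=cal.I_e, tau_e=1.3e-3, test_lag=0.25)
print(f"calibrated I_e = {cal.I_e:.1f} s^-1")
print("mean quanta per pulse:", [round(v, 1) for v in res.mean_counts])
m = res.mean_counts
print("normalized to pulse 1:", [round(v, 2) for v in m / m[0]])
```

prints

```
calibrated I_e = 500.0 s^-1
mean quanta per pulse: [303.9, 888.8, 1134.4, 299.0]
normalized to pulse 1: [1.0, 2.93, 3.73, 0.98]
```

Pulse 1 releases ~300 vesicles (the 3% anchor).  Pulses 2 and 3 release
2.9× and 3.7× more — facilitation, driven by the transient surplus of
preprimed and primed vesicles that the conditioning transients created.
By the test pulse 250 ms later that surplus has decayed and ~24% of the
pool sits unrecycled in the fused state, so the response falls below
baseline — depression.  The same machinery exposes spontaneous recordings
(`run_spontaneous`), low-probability impulse series with Poisson quantal
statistics (`run_impulse_series`, `analysis.poisson_test`), and
facilitation/depression lag sweeps (`run_lag_sweep`).

A CLI mirrors the library:

```sh
vesikin run --preset cat4 --protocol spontaneous --duration 300 --seed 1 --out out/
vesikin calibrate --preset frog4 --tau-e-ms 1.3 --target 0.03
vesikin analyze out/events.csv
```

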