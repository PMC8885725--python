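# Methods

## Model

Each vesicle is an independent continuous-time Markov chain on the serial
states of its fusion complex: docked (D), optionally one or two further
docked-like states (D2, D3), preprimed (pP), primed (P) and fused (F).
The maturation pairs `D ⇌ pP ⇌ P` are bidirectional; fusion `P → F` and
recycling `F → D` are unidirectional.  The supported chain lengths are
3–6 states: the 3-state chain removes pP, the 5/6-state chains insert
D2/D3 between D and pP with the same α/β₁ pair.  The pool is closed
(conserved N₀); a fused vesicle re-enters the docked pool at rate ρ, which
stands in for recycling plus resupply from the reserve pool.

Assumptions worth stating explicitly:

- all vesicles are identical and independent (no spatial structure, no
  heterogeneous subpools, no per-vesicle identity);
- all forward transitions share one rate constant α, and all backward
  transitions one β per pair (β᎐ = λ᎐·α); the shipped presets are
  `cat4` (α=0.62, β=62, λ=100, ρ=1 s⁻¹), `frog4` (0.3, 15, 50, 1),
  `frog5` (0.62, 13.0, λ≈21, 1), `frog6` (1.43, 9.5, λ=13, 1).  Where a
  tabulated β disagrees with λ·α in the last digit, the tabulated β is
  stored;
- the impulse-evoked calcium elevation is an instantaneous step of
  amplitude I_e (s⁻¹) decaying exponentially with τ_e (0.05–1.5 ms across
  protocols), coupled *additively* to every forward rate constant:
  α_s = α + f(t).  Successive transients superpose (residual-calcium
  convention); with millisecond τ_e and ≥30 ms between pulses the
  difference from a reset convention is below 10⁻⁸ relative.  I_e is
  treated as a rate increment because that is the only dimensionally
  consistent reading of α_s = α + f(t);
- calcium buffering, channel gating and activity-dependent modulation of
  the calcium current itself are not modelled.

## Exact stochastic simulation with time-varying rates

Propensities are `a_j(x,t) = (rate_j + f(t)·coupled_j)·x[source_j]`.
Between pulse onsets f(t) is non-increasing, so the total propensity
evaluated at the current time bounds the future total on the whole
remaining interval.  The engine draws a candidate waiting time from that
bound (`τ = −ln r₁ / a₀`), advances to the candidate time, accepts it with
probability `a₀(t+τ)/a₀(t)` (thinning), caps every step at the next pulse
onset (where f jumps upward and the bound is refreshed), and on acceptance
selects the transition from the cumulative propensities evaluated at the
accepted time (smallest j with `Σ_{k≤j} a_k > r₂ a₀`).  With f ≡ 0 the
thinning draw is skipped and the loop is the classical direct method with
exactly two uniforms per step.  RNG: one MT19937 stream per simulation
call, seeded explicitly; uniforms are consumed as (r₁[, accept][, r₂]) per
candidate step, so a (seed, configuration) pair reproduces an event log
bit-for-bit.  Trial batches derive child seeds from the master seed with
`numpy.random.SeedSequence`.

A "naive" mode freezes propensities at each step start — the literal
application of the homogeneous formulas to time-varying rates.  On a
3%-release pulse it overshoots the exact expectation by a few tenths of a
percent of the pool (detectable at 500 trials); it is retained only for
comparison.

Event logs record every executed transition (time + transition id), or
only fusions when memory matters; occupancy traces, quantal counts,
asynchronous release and final states are all pure functions of the log.

## Mean-field companion as a strict oracle

Because every propensity is linear in the state, the expected occupancies
obey `dx/dt = K(f(t)) x` exactly — for this model the "mean-field" is the
exact first moment, not an approximation.  The package solves the
stationary flux balance analytically and integrates the ODEs piecewise
between pulse onsets (LSODA, rtol 1e-9, first step τ_e/10 after an onset;
an auxiliary component accumulates the expected fusion count).  This
yields three things:

1. a correctness oracle: SSA time-averaged occupancies and post-pulse
   trial-mean fusion counts must match the ODE within Monte Carlo error
   (the test suite checks 3 SE at N₀ = 1,000 with 500 trials);
2. exact equilibration: a closed pool of independent vesicles has a
   multinomial stationary law over the stationary fractions, so the
   fast equilibration mode draws the multinomial and then burns in 10 s of
   simulation as a safeguard (the slower mode reproduces the 300-s
   burn-in from an all-docked start);
3. deterministic calibration (next section).

## Calibration of the transient amplitude

Published protocols quote τ_e but leave I_e in arbitrary units, so I_e is
reconstructed by bisection against an anchor, using the mean-field
expected release (exact in expectation, noise-free); an SSA-trial
evaluator with a fixed seed schedule is available as a cross-check.  The
expected single-pulse release fraction is monotone non-decreasing in I_e
(verified by sweep), which justifies bisection.  Anchors:

- **3% of the pool on one impulse** for the conditioning-train protocol
  (τ_e = 1.3 ms → I_e ≈ 500 s⁻¹) — the one release fraction the
  literature states for this preparation;
- **m ≈ 1 quantum per impulse** (release fraction 10⁻⁴) for the
  low-probability impulse series at τ_e = 0.15 ms, which produces about
  five count classes including failures;
- **peak facilitation ratio 2.5 at a 30-ms test lag** for the lag-sweep
  protocols, anchored at baseline recycling (ρ = 1 s⁻¹) and reused
  unchanged for the ρ = 0.1 and ρ = 10 s⁻¹ variants.  No release fraction
  is documented for these high-probability experiments; 2.5 is the
  classic magnitude of short-lag train facilitation at the frog
  neuromuscular junction, and the resulting single-impulse release
  (~5% of the pool) is consistent with a high-probability condition.  The
  facilitation ratio is non-monotone in I_e (it returns to 1 at both
  extremes); the calibration brackets the physiologically relevant
  falling branch.  The anchor value is config-exposed.

## Protocols and counting conventions

The synchronous response to a pulse is the fusion count in a window
`[t_s, t_s + 10·τ_e)`, truncated at the next pulse onset; 10 τ_e captures
>99.99% of the transient-driven hazard.  Fusions outside every window are
"asynchronous".  The impulse series runs as one continuous session with a
5-s recovery between stimuli (≥5 pool relaxation times at ρ = 1);
train/test protocols use independent equilibrated trials.  Lag sweeps
report `N_test/N_1cond` as the ratio of trial means, with a delta-method
standard error using the within-trial covariance.  The conditioning train
is 3 pulses at 30-ms intervals throughout; lags are measured from the
last conditioning pulse.

## Statistical conventions

- **Interval distribution**: τ estimated by maximum likelihood on raw
  intervals (the sample mean; SE τ/√n) rather than by fitting binned
  counts; the binned model `n_T(Δt/τ)e^(−t/τ)` is still produced for
  display and χ² comparison.
- **Poisson test**: m is the sample mean; expected class counts
  `n·e^(−m)m^x/x!` with the upper tail folded into the top class, top
  classes pooled until every expected count ≥ 1, Pearson χ² with
  dof = classes − 2.  The pooling threshold is an argument.
- **Cooperativity**: least-squares fit of `m = k(τ_e/(1+τ_e/K))^n` at
  fixed integer order n ∈ {3,4}, τ_e standing in for the calcium
  concentration; R² reported.
- **Release time course**: `m/m_max = (1+A)e^(−u) − A e^(−u/x)` over
  u = t/τ_e with x < 1, so the second (faster) exponential only shapes
  u < 1 — the release latency contributed by vesicles maturing from
  immature states during the transient.
- **Facilitation decay**: fit of `ratio − 1` to
  `B_f e^(−t/τ_fast) + B_s e^(−t/τ_slow)` with non-negative amplitudes
  and τ_fast < τ_slow enforced structurally (τ_slow = τ_fast + δ, δ > 0);
  multi-start least squares keeps the best residual.  A fit whose
  amplitude ratio or constant separation collapses is flagged
  `single_exponential`.

## Known limitations

- **The two-exponential facilitation fit is ill-conditioned on this
  model's data.**  The relaxation spectrum of the frog 4-state generator
  at ρ = 10 s⁻¹ is {57, 75, 100 ms}; since the expected dynamics are
  linear, the expected facilitation curve decays as a fixed combination
  of exactly these modes, empirically ≈ a single 77-ms exponential.  Any
  two-exponential description of such a curve lies on a degenerate ridge:
  widely separated constant pairs (e.g. ~30 and ~170 ms) fit almost as
  well (R² ≈ 0.98) as the true single constant, and the constants
  returned for noisy sweeps are initialization- and noise-sensitive.  The
  package reports the ridge optimum and the `single_exponential` flag
  rather than privileging any particular pair; no component slower than
  100 ms can be genuine at ρ = 10.
- Per-impulse quantal counts stay near-Poisson whenever per-vesicle
  fusion probabilities are small, even for parameter settings (small λ₁)
  that inflate m several-fold; the robust signature of small λ₁ is the
  extended class range, not a reliable Pearson rejection.
- The simulator generates data from the model itself; passing tests show
  internal consistency (engine ↔ master equation ↔ mean field) and
  reproduction of the published simulated magnitudes, not validity of the
  kinetic scheme for real terminals.  Real recordings add postsynaptic
  quantal amplitude variability, electrode noise and non-stationary
  calcium dynamics, none of which are emulated.
- Mean inter-event statistics assume stationarity; the spontaneous
  "frequency" of classic reports is ambiguous (count rate vs mean
  reciprocal interval), so both are reported.

## Problem sizes

The shipped acceptance computation uses: one 300-s equilibrated run for
the resting occupancy; 150 trials for the conditioning-train release;
9 lags × 120 trials for the facilitation-decay sweep; 200 trials for the
slow-recycling depression ratio; 20 × 250-stimulus series for the Poisson
median p; 9 τ_e values × 200 trials for the cooperativity sweep; a 600-s
recording for the spontaneous interval constant.  These sizes keep every
Monte Carlo standard error well inside the tolerance it is compared
against while completing in minutes on one core.
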