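"""Deterministic mean-field companion of the stochastic scheme.

Every propensity of the jump process is linear in the state (each vesicle
is an independent Markov chain), so the mean occupancies obey the linear
ODE system ``dx/dt = K(f(t)) x`` *exactly* — the mean-field here is not an
approximation but the exact expectation of the stochastic process.  This
makes it a strict oracle for the simulation engine: time-averaged
occupancies must converge to the analytic steady state, and mean fusion
counts after a pulse must match the integrated ODE within Monte Carlo
error.

The stationary distribution of a closed network of independent particles
is multinomial over the steady-state fractions, which the engine exploits
for fast equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .scheme import KineticScheme
from .stimulus import NO_STIMULUS, StimulusProtocol

__all__ = ["SteadyState", "MeanFieldTrajectory", "rate_matrix",
           "steady_state", "integrate", "expected_release"]


@dataclass(frozen=True)
class SteadyState:
    """Stationary expected occupancies and fusion flux."""

    counts: np.ndarray          # expected count per state (real-valued)
    fractions: np.ndarray       # counts / n_total
    fusion_flux: float          # expected fusions per second (= alpha * P*)


def rate_matrix(scheme: KineticScheme, f_value: float = 0.0) -> np.ndarray:
    """Generator matrix K with ``dx/dt = K x`` at calcium increment f."""
    n = scheme.n_states
    K = np.zeros((n, n))
    rates = scheme.base_rates + f_value * scheme.coupled_mask
    src, dst = scheme.source_indices, scheme.target_indices
    for j in range(scheme.n_transitions):
        K[src[j], src[j]] -= rates[j]
        K[dst[j], src[j]] += rates[j]
    return K


def steady_state(scheme: KineticScheme, n_total: int) -> SteadyState:
    """Exact stationary solution of the flux-balance system.

    Solves ``K pi = 0`` with the normalisation ``sum(pi) = 1`` (one balance
    row replaced by the conservation constraint).
    """
    K = rate_matrix(scheme, 0.0)
    n = scheme.n_states
    A = K.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular flux-balance system") from exc
    if (pi < -1e-12).any():
        raise ValueError(f"negative stationary fraction: {pi}")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    p_idx = scheme.state_index("P")
    flux = scheme.base_rates[scheme.fusion_index] * pi[p_idx] * n_total
    return SteadyState(counts=pi * n_total, fractions=pi, fusion_flux=float(flux))


@dataclass(frozen=True)
class MeanFieldTrajectory:
    """Expected occupancies over time plus cumulative expected fusions."""

    t: np.ndarray
    counts: np.ndarray            # shape (len(t), n_states)
    cumulative_fusions: np.ndarray

    def cumulative_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.cumulative_fusions))


def integrate(scheme: KineticScheme, protocol: StimulusProtocol, t_end: float,
              n_total: int, y0: np.ndarray | None = None,
              t_start: float = 0.0, rtol: float = 1e-9, atol: float = 1e-9,
              n_grid: int = 200) -> MeanFieldTrajectory:
    """Integrate the mean occupancy ODEs with time-dependent forward rates.

    Integration proceeds piecewise between pulse onsets (where f jumps up);
    within a segment the transient decay is smooth and LSODA handles the
    stiffness of millisecond transients against second-scale kinetics.
    An auxiliary component accumulates the expected fusion count
    ``integral (alpha + f) P dt``.
    """
    if y0 is None:
        y0 = steady_state(scheme, n_total).counts
    n = scheme.n_states
    p_idx = scheme.state_index("P")
    alpha_f = scheme.base_rates[scheme.fusion_index]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        f = protocol.transient_value(t)
        K = rate_matrix(scheme, f)
        dy = np.empty(n + 1)
        dy[:n] = K @ y[:n]
        dy[n] = (alpha_f + f) * y[p_idx]
        return dy

    onsets = [p.t_s for p in protocol.pulses if t_start < p.t_s < t_end]
    breaks = [t_start] + onsets + [t_end]
    y = np.concatenate([np.asarray(y0, dtype=float), [0.0]])
    ts_out = [np.array([t_start])]
    ys_out = [y[None, :].copy()]
    for a, b in zip(breaks, breaks[1:]):
        if b <= a:
            continue
        t_eval = np.linspace(a, b, max(2, int(n_grid * (b - a) / (t_end - t_start)) + 2))
        min_tau = min((p.tau_e for p in protocol.pulses if p.t_s <= a + 1e-15),
                      default=b - a)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval, first_step=min(min_tau / 10.0, (b - a) / 10.0))
        if not sol.success:
            raise RuntimeError(f"mean-field integration failed: {sol.message}")
        y = sol.y[:, -1]
        ts_out.append(sol.t[1:])
        ys_out.append(sol.y.T[1:])
    t = np.concatenate(ts_out)
    Y = np.concatenate(ys_out, axis=0)
    return MeanFieldTrajectory(t=t, counts=Y[:, :n], cumulative_fusions=Y[:, n])


def expected_release(scheme: KineticScheme, protocol: StimulusProtocol,
                     t_end: float, n_total: int,
                     t_from: float = 0.0) -> float:
    """Expected number of fusions in ``[t_from, t_end]`` starting from the
    stationary state at t = 0.

    Both endpoints are integrated to exactly (no grid interpolation), so
    narrow response windows are resolved at solver accuracy.
    """
    c_end = integrate(scheme, protocol, t_end, n_total).cumulative_fusions[-1]
    if t_from <= 0.0:
        return float(c_end)
    c_from = integrate(scheme, protocol, t_from, n_total).cumulative_fusions[-1]
    return float(c_end - c_from)
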