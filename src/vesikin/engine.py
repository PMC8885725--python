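"""Statistically exact stochastic simulation of the vesicle pool.

The solver realises the jump process whose master equation governs the
pool occupancy distribution: at state x, transition j fires with
propensity ``a_j(x, t) = (rate_j + f(t) * coupled_j) * x[source_j]``.
Waiting times and transition choices follow the direct (first-reaction
free) algorithm — ``tau = -ln(r1)/a0`` and the smallest j whose cumulative
propensity exceeds ``r2 * a0`` — made exact under time-varying f(t) by
thinning against the monotone upper bound available between pulse onsets
(see :mod:`vesikin._kernels`).

Event logs record every executed transition (or only fusions, on request)
so that occupancy traces, quantal counts and asynchronous release can all
be recomputed from the log alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .meanfield import steady_state
from .scheme import KineticScheme, PoolState, PropensityVector, all_docked
from .stimulus import NO_STIMULUS, StimulusProtocol

__all__ = ["SsaStep", "EventLog", "sample_step_homogeneous", "simulate",
           "equilibrate", "spawn_seeds"]

_RECORD = {"none": _kernels.RECORD_NONE,
           "fusions": _kernels.RECORD_FUSIONS,
           "all": _kernels.RECORD_ALL}


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) & np.uint32(0x7FFFFFFF)).astype(np.int64)


@dataclass(frozen=True)
class SsaStep:
    """One sampled jump: waiting time, chosen transition and the uniforms."""

    tau: float
    j: int
    r1: float
    r2: float


def sample_step_homogeneous(prop: PropensityVector, r1: float, r2: float) -> SsaStep | None:
    """Single step of the homogeneous direct method.

    ``tau = -ln(r1)/a0``; ``j`` is the smallest index whose cumulative
    propensity exceeds ``r2 * a0``.  Returns None when ``a0 == 0`` (no
    transition can fire; the caller advances to the next discontinuity).
    """
    if not (0.0 < r1 < 1.0 and 0.0 < r2 < 1.0):
        raise ValueError("r1, r2 must lie in (0, 1)")
    if prop.a0 <= 0.0:
        return None
    tau = -math.log(r1) / prop.a0
    cumulative = np.cumsum(prop.a)
    j = int(np.searchsorted(cumulative, r2 * prop.a0, side="right"))
    j = min(j, len(prop.a) - 1)
    return SsaStep(tau=tau, j=j, r1=r1, r2=r2)


@dataclass
class EventLog:
    """Time-stamped record of executed transitions over one run."""

    times: np.ndarray
    transition_ids: np.ndarray
    scheme: KineticScheme
    t_start: float
    t_end: float
    seed: int
    initial_counts: np.ndarray
    final_counts: np.ndarray
    record: str = "all"

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def fusion_times(self) -> np.ndarray:
        if self.record == "fusions":
            return self.times
        return self.times[self.transition_ids == self.scheme.fusion_index]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def replay_final_counts(self) -> np.ndarray:
        """Re-derive the final occupancy by applying every logged change
        vector to the initial state (only meaningful for record='all')."""
        if self.record != "all":
            raise ValueError("replay requires a full transition log")
        if self.n_events == 0:
            return self.initial_counts.copy()
        return self.initial_counts + self.scheme.change_vectors[self.transition_ids].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        labels = np.array(self.scheme.labels())
        return pd.DataFrame({
            "t_seconds": self.times,
            "transition_id": self.transition_ids,
            "transition_label": labels[self.transition_ids],
            "is_fusion": self.transition_ids == self.scheme.fusion_index,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _estimate_capacity(scheme: KineticScheme, initial: PoolState,
                       duration: float, protocol: StimulusProtocol) -> int:
    """Rough upper estimate of the number of events, used to size buffers."""
    prop = (scheme.base_rates * steady_state(scheme, max(initial.n_total, 1)).counts[
        scheme.source_indices]).sum()
    pulse_load = sum(p.I_e * p.tau_e for p in protocol.pulses) * initial.n_total * 3.0
    est = prop * duration * 1.6 + pulse_load + 10_000
    return int(min(est, 300_000_000))


def simulate(scheme: KineticScheme, protocol: StimulusProtocol, t_end: float,
             seed: int, initial: PoolState, *, method: str = "exact",
             record: str = "all") -> tuple[EventLog, PoolState]:
    """Simulate the pool from ``initial`` (at its own time) until ``t_end``.

    Parameters
    ----------
    method
        "exact" (thinning against the monotone bound; the default) or
        "naive" (propensities frozen at each step start, for comparison).
    record
        "all" logs every transition, "fusions" only fusion events,
        "none" nothing (state evolution only).

    Returns the event log and the final pool state.  Same seed, same
    configuration => bit-identical log.
    """
    if method not in ("exact", "naive"):
        raise ValueError(f"unknown method {method!r}")
    if record not in _RECORD:
        raise ValueError(f"unknown record mode {record!r}")
    if t_end <= initial.t:
        raise ValueError("t_end must exceed the initial state's time")
    t_s, I_e, tau_e = protocol.arrays()
    cap = _estimate_capacity(scheme, initial, t_end - initial.t, protocol)
    if record == "fusions":
        cap = max(int(cap / 100), 10_000)
    if record == "none":
        cap = 1
    x = initial.counts.astype(np.int64).copy()
    while True:
        ev_t = np.empty(cap, dtype=np.float64)
        ev_j = np.empty(cap, dtype=np.int32)
        status, ne, t_final = _kernels.ssa_kernel(
            scheme.source_indices, scheme.target_indices, scheme.base_rates,
            scheme.coupled_mask, x, initial.t, t_end, t_s, I_e, tau_e,
            int(seed), method == "exact", _RECORD[record],
            scheme.fusion_index, ev_t, ev_j)
        if status == _kernels.OK:
            break
        cap *= 4
        x = initial.counts.astype(np.int64).copy()
    if (x < 0).any():
        raise RuntimeError(f"negative occupancy after simulation: {x}")
    log = EventLog(times=ev_t[:ne].copy(), transition_ids=ev_j[:ne].copy(),
                   scheme=scheme, t_start=initial.t, t_end=t_end,
                   seed=int(seed), initial_counts=initial.counts.copy(),
                   final_counts=x.copy(), record=record)
    return log, PoolState(x, t_end)


def equilibrate(scheme: KineticScheme, n_total: int, seed: int,
                mode: str = "fast", burn_in: float = 10.0) -> PoolState:
    """Draw a stationary pool state.

    mode "cold": start with every vesicle docked and simulate 300 s (the
    distribution is stationary well before that).  mode "fast": draw the
    occupancy from the multinomial over the mean-field stationary fractions
    — the exact stationary law for a closed pool of independent vesicles —
    then burn in ``burn_in`` seconds of simulation as a safeguard.
    """
    seeds = spawn_seeds(seed, 2)
    if mode == "cold":
        _, state = simulate(scheme, NO_STIMULUS, 300.0, int(seeds[1]),
                            all_docked(scheme, n_total), record="none")
    elif mode == "fast":
        rng = np.random.default_rng(int(seeds[0]))
        counts = rng.multinomial(n_total, steady_state(scheme, n_total).fractions)
        state = PoolState(counts.astype(np.int64), 0.0)
        if burn_in > 0:
            _, state = simulate(scheme, NO_STIMULUS, burn_in, int(seeds[1]),
                                state, record="none")
    else:
        raise ValueError(f"unknown equilibration mode {mode!r}")
    state.t = 0.0
    return state


def time_averaged_occupancy(log: EventLog) -> np.ndarray:
    """Time-weighted mean occupancy per state over the logged interval."""
    if log.record != "all":
        raise ValueError("time average requires a full transition log")
    return _kernels.occupancy_time_average(
        log.times, log.transition_ids.astype(np.int64),
        log.scheme.change_vectors, log.initial_counts, log.t_start, log.t_end)
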