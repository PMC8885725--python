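"""Numba-compiled inner loops of the stochastic simulation engine.

The jump process is time-inhomogeneous: calcium-coupled propensities carry
the factor ``rate + f(t)`` with f piecewise given by decaying pulse
transients.  Between pulse onsets f(t) is non-increasing, so the total
propensity evaluated at the current time is a valid upper bound for the
whole remaining interval.  The exact sampler draws candidate waiting times
from that bound, thins them with acceptance probability
``a0(t + tau) / a0(t)``, and caps every step at the next pulse onset
(where f jumps upward and the bound must be refreshed).  With f identically
zero the thinning step is skipped and the loop reduces to the classical
homogeneous algorithm (one uniform for the waiting time, one for the
transition choice).

The "naive" variant freezes propensities at the start of each step — the
literal application of the homogeneous formulas to time-varying rates —
and is provided for comparison only.

Random numbers come from numba's internal MT19937 stream seeded once per
kernel call, so a (seed, configuration) pair reproduces an event log
bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
OVERFLOW = 1

# record modes
RECORD_NONE = 0
RECORD_FUSIONS = 1
RECORD_ALL = 2

# pulses older than this many decay constants contribute < 3e-20 of I_e
# and are dropped from the running transient sum
_CUTOFF = 45.0


@njit(cache=False)
def _transient(t, t_s, I_e, tau_e, lo, hi):
    f = 0.0
    for k in range(lo, hi):
        f += I_e[k] * np.exp(-(t - t_s[k]) / tau_e[k])
    return f


@njit(cache=False)
def ssa_kernel(src, dst, rates, coupled, x, t0, t_end,
               t_s, I_e, tau_e, seed, exact, record_mode, fusion_j,
               ev_t, ev_j):
    """Advance the pool from t0 to t_end, mutating ``x`` in place.

    Returns (status, n_events, t_final).  ``ev_t``/``ev_j`` are
    caller-allocated buffers; OVERFLOW is returned when they fill up, in
    which case the caller re-runs with a larger buffer (same seed, same
    trajectory).
    """
    np.random.seed(seed)
    m = src.shape[0]
    n_pulse = t_s.shape[0]
    cap = ev_t.shape[0]
    ne = 0
    t = t0
    # pulses already past their onset at t0
    hi = 0
    while hi < n_pulse and t_s[hi] <= t:
        hi += 1
    lo = 0
    while t < t_end:
        while lo < hi and (t - t_s[lo]) > _CUTOFF * tau_e[lo]:
            lo += 1
        t_next = t_end
        if hi < n_pulse and t_s[hi] < t_end:
            t_next = t_s[hi]
        f = _transient(t, t_s, I_e, tau_e, lo, hi)
        a0 = 0.0
        for j in range(m):
            r = rates[j]
            if coupled[j]:
                r += f
            a0 += r * x[src[j]]
        if a0 <= 0.0:
            t = t_next
            if hi < n_pulse and t_next == t_s[hi]:
                hi += 1
            continue
        r1 = np.random.random()
        tau = -np.log(r1) / a0
        if t + tau >= t_next:
            t = t_next
            if hi < n_pulse and t_next == t_s[hi]:
                hi += 1
            continue
        t_new = t + tau
        if exact and f > 0.0:
            f2 = _transient(t_new, t_s, I_e, tau_e, lo, hi)
            # coupled source mass: a0 shrinks linearly with f
            cm = 0.0
            for j in range(m):
                if coupled[j]:
                    cm += x[src[j]]
            a0_new = a0 - (f - f2) * cm
            u = np.random.random()
            if u * a0 > a0_new:
                t = t_new  # thinned candidate: time advances, no event
                continue
        else:
            f2 = f
            a0_new = a0
        r2 = np.random.random()
        threshold = r2 * a0_new
        c = 0.0
        chosen = -1
        for j in range(m):
            r = rates[j]
            if coupled[j]:
                r += f2
            c += r * x[src[j]]
            if c > threshold:
                chosen = j
                break
        if chosen < 0:
            # rounding: fall back to the last transition with occupied source
            for j in range(m - 1, -1, -1):
                if x[src[j]] > 0:
                    chosen = j
                    break
            if chosen < 0:
                return OK, ne, t_new  # nothing can fire
        x[src[chosen]] -= 1
        x[dst[chosen]] += 1
        t = t_new
        if record_mode == RECORD_ALL or (record_mode == RECORD_FUSIONS
                                         and chosen == fusion_j):
            if ne >= cap:
                return OVERFLOW, ne, t
            ev_t[ne] = t
            ev_j[ne] = chosen
            ne += 1
    return OK, ne, t


@njit(cache=False)
def occupancy_time_average(ev_t, ev_j, change_vectors, x0, t0, t1):
    """Time-weighted average occupancy per state over [t0, t1] from a full
    transition log starting at occupancy ``x0``."""
    n = x0.shape[0]
    acc = np.zeros(n)
    x = x0.astype(np.float64).copy()
    t_prev = t0
    for i in range(ev_t.shape[0]):
        dt = ev_t[i] - t_prev
        for s in range(n):
            acc[s] += x[s] * dt
        for s in range(n):
            x[s] += change_vectors[ev_j[i], s]
        t_prev = ev_t[i]
    dt = t1 - t_prev
    for s in range(n):
        acc[s] += x[s] * dt
    return acc / (t1 - t0)
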