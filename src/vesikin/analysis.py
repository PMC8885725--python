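"""Quantal-release statistics.

Interval distributions of spontaneous fusion events, Poisson goodness of
fit for per-impulse quantal counts, calcium-cooperativity fits of the
Dodge–Rahamimoff form, the biexponential time course of normalized
release, facilitation-decay fits, and occupancy dynamics recovered from
event logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import EventLog

__all__ = [
    "IntervalFit", "QuantalStatistics", "CooperativityFit",
    "ReleaseTimeCourseFit", "FacilitationDecayFit",
    "fit_interval_distribution", "poisson_test", "fit_cooperativity",
    "fit_release_time_course", "fit_facilitation_decay",
    "occupancy_fractions", "mepp_frequency",
]


@dataclass(frozen=True)
class IntervalFit:
    """Exponential fit of the inter-event-interval distribution.

    ``tau`` is the maximum-likelihood time constant (the sample mean of the
    raw intervals); the binned model counts follow
    ``n(t) = n_T * (dt / tau) * exp(-t / tau)``, the display form used for
    miniature end-plate potential interval histograms.
    """

    tau: float
    tau_se: float
    n_T: int
    bin_width: float
    bin_edges: np.ndarray
    observed: np.ndarray
    model: np.ndarray
    degenerate: bool = False


def fit_interval_distribution(event_times: np.ndarray,
                              bin_width: float = 0.5) -> IntervalFit:
    """MLE of the exponential interval constant plus binned model counts.

    Requires at least 20 events.  The MLE is bin-free (tau = mean interval,
    standard error tau/sqrt(n)); binned counts are produced only for
    display and chi-square comparison.
    """
    event_times = np.sort(np.asarray(event_times, dtype=float))
    if len(event_times) < 20:
        raise ValueError(f"need >= 20 events, got {len(event_times)}")
    intervals = np.diff(event_times)
    n = len(intervals)
    tau = float(intervals.mean())
    degenerate = intervals.std() < 1e-12 * max(tau, 1e-300)
    edges = np.arange(0.0, intervals.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    observed, _ = np.histogram(intervals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = n * (bin_width / tau) * np.exp(-centers / tau)
    return IntervalFit(tau=tau, tau_se=tau / np.sqrt(n), n_T=n,
                       bin_width=bin_width, bin_edges=edges,
                       observed=observed, model=model, degenerate=degenerate)


@dataclass(frozen=True)
class QuantalStatistics:
    """Per-impulse quantal counts against the Poisson prediction."""

    counts: np.ndarray
    m: float                      # mean quanta per impulse
    classes: np.ndarray           # class values after tail pooling
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    dof: int
    p: float
    degenerate: bool = False


def poisson_test(counts: np.ndarray, pool_threshold: float = 1.0) -> QuantalStatistics:
    """Pearson chi-square test of per-trial quantal counts against
    Poisson(m) with m estimated as the sample mean.

    Upper-tail classes are pooled until every expected count reaches
    ``pool_threshold``; degrees of freedom are (#classes - 2), accounting
    for the estimated mean and the total. Requires >= 50 trials.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if len(counts) < 50:
        raise ValueError(f"need >= 50 trials, got {len(counts)}")
    n = len(counts)
    m = float(counts.mean())
    if m == 0.0:
        return QuantalStatistics(counts=counts, m=0.0,
                                 classes=np.array([0]), observed=np.array([n]),
                                 expected=np.array([float(n)]), chi2=0.0,
                                 dof=0, p=np.nan, degenerate=True)
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    pk = stats.poisson.pmf(ks, m)
    pk[-1] += stats.poisson.sf(kmax, m)  # fold the upper tail into the top class
    observed = np.bincount(counts, minlength=kmax + 1).astype(float)
    expected = n * pk
    # pool top classes until every expected count reaches the threshold
    while len(expected) > 2 and expected[-1] < pool_threshold:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected = expected[:-1]
        observed = observed[:-1]
        ks = ks[:-1]
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = max(len(expected) - 2, 1)
    p = float(stats.chi2.sf(chi2, dof))
    return QuantalStatistics(counts=counts, m=m, classes=ks,
                             observed=observed, expected=expected,
                             chi2=chi2, dof=dof, p=p)


@dataclass(frozen=True)
class CooperativityFit:
    """Dodge–Rahamimoff cooperative saturation fit of quantal content.

    ``m = k * (x / (1 + x / K)) ** n`` with the calcium-transient decay
    time standing in for the calcium concentration; n is the cooperativity
    order (3 or 4).
    """

    order: int
    k: float
    K: float
    r_squared: float
    fitted: np.ndarray


def fit_cooperativity(tau_e: np.ndarray, m: np.ndarray,
                      order: int = 3) -> CooperativityFit:
    """Least-squares Dodge–Rahamimoff fit of m(tau_e) at fixed order."""
    if order not in (3, 4):
        raise ValueError("cooperativity order must be 3 or 4")
    tau_e = np.asarray(tau_e, dtype=float)
    m = np.asarray(m, dtype=float)
    if len(tau_e) < 5:
        raise ValueError("need >= 5 (tau_e, m) points")

    def model(x: np.ndarray, k: float, K: float) -> np.ndarray:
        return k * (x / (1.0 + x / K)) ** order

    k0 = m.max() / (tau_e.max() ** order)
    best = None
    for K0 in (tau_e.max(), tau_e.max() * 10, tau_e.mean()):
        try:
            popt, _ = optimize.curve_fit(model, tau_e, m, p0=[k0, K0],
                                         bounds=([0, 1e-12], [np.inf, np.inf]),
                                         maxfev=20000)
        except RuntimeError:
            continue
        resid = m - model(tau_e, *popt)
        ss = float((resid ** 2).sum())
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        raise RuntimeError("cooperativity fit did not converge")
    popt, ss = best
    sst = float(((m - m.mean()) ** 2).sum())
    r2 = 1.0 - ss / sst if sst > 0 else 0.0
    return CooperativityFit(order=order, k=float(popt[0]), K=float(popt[1]),
                            r_squared=r2, fitted=model(tau_e, *popt))


@dataclass(frozen=True)
class ReleaseTimeCourseFit:
    """Two-exponential decay of normalized release versus t / tau_e:
    ``m/m_max = (1 + A) exp(-u) - A exp(-u / x)`` with ``x < 1``.

    The second exponential (amplitude A, time-constant ratio x) is faster
    than the primary decay, so it shapes the curve only below u = 1 — it
    reports the maturation transitions that precede fusion (the release
    latency contributed by vesicles arriving from immature states).
    """

    A: float
    x: float
    r_squared: float
    fitted: np.ndarray


def fit_release_time_course(u: np.ndarray, y: np.ndarray) -> ReleaseTimeCourseFit:
    """Fit normalized release y(u), u = t / tau_e; needs points on both
    sides of u = 1."""
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(u) < 8:
        raise ValueError("need >= 8 points")
    if not ((u < 1).any() and (u > 1).any()):
        raise ValueError("points must span u < 1 and u > 1")

    def model(uu: np.ndarray, A: float, x: float) -> np.ndarray:
        return (1.0 + A) * np.exp(-uu) - A * np.exp(-uu / x)

    popt, _ = optimize.curve_fit(model, u, y, p0=[0.3, 0.3],
                                 bounds=([-0.999, 1e-3], [50.0, 0.999]),
                                 maxfev=20000)
    resid = y - model(u, *popt)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
    return ReleaseTimeCourseFit(A=float(popt[0]), x=float(popt[1]),
                                r_squared=r2, fitted=model(u, *popt))


@dataclass(frozen=True)
class FacilitationDecayFit:
    """Constrained two-exponential decay of the facilitation ratio:
    ``ratio(t) = 1 + B_f exp(-t/tau_fast) + B_s exp(-t/tau_slow)`` with
    ``tau_fast < tau_slow`` and non-negative amplitudes (full recovery to 1
    is imposed, so the fit acts on ratio - 1)."""

    B_fast: float
    B_slow: float
    tau_fast: float
    tau_slow: float
    r_squared: float
    single_exponential: bool      # True when one amplitude collapsed to ~0


def fit_facilitation_decay(lags: np.ndarray, ratio: np.ndarray,
                           weights: np.ndarray | None = None) -> FacilitationDecayFit:
    """Fit the facilitation decay over test-pulse lags.

    Multi-start least squares on ``ratio - 1``; the slow constant is
    parameterised as ``tau_fast + delta`` (delta > 0) so the ordering
    constraint is structural.  When the best fit drives one amplitude to
    zero the decay is effectively single-exponential and flagged as such.
    """
    lags = np.asarray(lags, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if len(lags) < 6:
        raise ValueError("need >= 6 lags")
    y = ratio - 1.0
    sigma = None if weights is None else 1.0 / np.asarray(weights)

    def model(t: np.ndarray, Bf: float, Bs: float, tf: float, delta: float) -> np.ndarray:
        return Bf * np.exp(-t / tf) + Bs * np.exp(-t / (tf + delta))

    amp = max(y.max(), 0.1)
    span = lags.max() - lags.min()
    best = None
    for tf0 in np.geomspace(lags.min() / 2, span, 8):
        for split in (0.3, 0.7):
            p0 = [amp * split, amp * (1 - split), tf0, tf0 * 4]
            try:
                popt, _ = optimize.curve_fit(
                    model, lags, y, p0=p0, sigma=sigma,
                    bounds=([0, 0, lags.min() / 20, 1e-6],
                            [1e3, 1e3, span * 10, span * 20]),
                    maxfev=30000)
            except RuntimeError:
                continue
            resid = y - model(lags, *popt)
            ss = float((resid ** 2).sum())
            if best is None or ss < best[1] * (1 - 1e-9):
                best = (popt, ss)
    if best is None:
        raise RuntimeError("facilitation decay fit did not converge")
    popt, ss = best
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss / sst if sst > 0 else 0.0
    Bf, Bs, tf, delta = popt
    ts = tf + delta
    total = Bf + Bs
    single = total > 0 and (min(Bf, Bs) / total < 1e-3 or delta / tf < 1e-2)
    return FacilitationDecayFit(B_fast=float(Bf), B_slow=float(Bs),
                                tau_fast=float(tf), tau_slow=float(ts),
                                r_squared=r2, single_exponential=bool(single))


def occupancy_fractions(log: EventLog, t_grid: np.ndarray) -> pd.DataFrame:
    """State-occupancy fractions sampled on ``t_grid`` from a full
    transition log; fractions sum to 1 at every sample point."""
    if log.record != "all":
        raise ValueError("occupancy requires a full transition log")
    t_grid = np.asarray(t_grid, dtype=float)
    n_total = log.initial_counts.sum()
    deltas = log.scheme.change_vectors[log.transition_ids]
    cum = np.vstack([np.zeros(log.scheme.n_states, dtype=np.int64),
                     np.cumsum(deltas, axis=0)])
    idx = np.searchsorted(log.times, t_grid, side="right")
    counts = log.initial_counts[None, :] + cum[idx]
    frac = counts / n_total
    df = pd.DataFrame(frac, columns=list(log.scheme.states))
    df.insert(0, "t_seconds", t_grid)
    return df


def mepp_frequency(log: EventLog) -> dict[str, float]:
    """Spontaneous fusion frequency.

    Primary statistic: event count / recording duration.  The mean of the
    reciprocal intervals is also reported ("instantaneous" frequency) —
    the two differ whenever intervals are dispersed, and published
    frequency figures do not always say which was used.
    """
    if log.duration <= 0:
        raise ValueError("log duration must be positive")
    times = log.fusion_times
    rate = len(times) / log.duration
    inst = np.nan
    if len(times) >= 2:
        intervals = np.diff(np.sort(times))
        intervals = intervals[intervals > 0]
        if len(intervals):
            inst = float(np.mean(1.0 / intervals))
    return {"count_rate": float(rate), "instantaneous": inst,
            "n_events": int(len(times))}
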