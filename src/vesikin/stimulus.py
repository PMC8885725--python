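"""Stimulus-evoked calcium transients and their coupling to forward rates.

Each presynaptic impulse at time ``t_s`` evokes an intracellular calcium
elevation modelled as an instantaneous step of amplitude ``I_e`` followed
by exponential decay with time constant ``tau_e``::

    f(t) = 0                              for t <  t_s
    f(t) = I_e * exp(-(t - t_s)/tau_e)    for t >= t_s

``I_e`` is a rate increment in s^-1: during the transient every
calcium-coupled forward rate constant becomes ``alpha_s = alpha + f(t)``.
Transients from successive pulses superpose additively (residual-calcium
convention); with millisecond decay times and tens of milliseconds between
pulses the cross-pulse residue is negligible.

All times are seconds.  Configuration layers may accept milliseconds and
convert on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pulse",
    "StimulusProtocol",
    "modulated_alpha",
    "periodic_train",
    "train_with_test",
    "NO_STIMULUS",
]


@dataclass(frozen=True)
class Pulse:
    """One impulse-evoked calcium transient (times in s, amplitude in s^-1)."""

    t_s: float
    I_e: float
    tau_e: float

    def __post_init__(self) -> None:
        if self.I_e < 0:
            raise ValueError("I_e must be non-negative")
        if not self.tau_e > 0:
            raise ValueError("tau_e must be positive")

    def value(self, t: float) -> float:
        if t < self.t_s:
            return 0.0
        return self.I_e * math.exp(-(t - self.t_s) / self.tau_e)


@dataclass(frozen=True)
class StimulusProtocol:
    """Time-ordered sequence of pulses with additive superposition."""

    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        onsets = [p.t_s for p in self.pulses]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("pulse onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pulses)

    def transient_value(self, t: float) -> float:
        """f(t): summed contribution of all pulses with ``t_s <= t``."""
        return sum(p.value(t) for p in self.pulses)

    def next_discontinuity(self, t: float) -> float | None:
        """Earliest pulse onset strictly after ``t`` (f steps up there)."""
        for p in self.pulses:
            if p.t_s > t:
                return p.t_s
        return None

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(onsets, amplitudes, decay constants) as float64 arrays."""
        t_s = np.array([p.t_s for p in self.pulses], dtype=np.float64)
        I_e = np.array([p.I_e for p in self.pulses], dtype=np.float64)
        tau_e = np.array([p.tau_e for p in self.pulses], dtype=np.float64)
        return t_s, I_e, tau_e

    def with_override(self, index: int, I_e: float | None = None,
                      tau_e: float | None = None) -> "StimulusProtocol":
        """Copy of the protocol with one pulse's amplitude/decay replaced
        (e.g. a briefer tau_e on the third conditioning impulse to emulate
        an intracellular calcium chelator)."""
        pulses = list(self.pulses)
        p = pulses[index]
        pulses[index] = Pulse(p.t_s,
                              p.I_e if I_e is None else I_e,
                              p.tau_e if tau_e is None else tau_e)
        return StimulusProtocol(tuple(pulses))

    def shifted(self, dt: float) -> "StimulusProtocol":
        return StimulusProtocol(tuple(Pulse(p.t_s + dt, p.I_e, p.tau_e)
                                      for p in self.pulses))


NO_STIMULUS = StimulusProtocol(())


def modulated_alpha(alpha: float, f_value: float) -> float:
    """Effective forward rate constant during a calcium transient."""
    if f_value < 0:
        raise ValueError("f_value must be non-negative")
    return alpha + f_value


def periodic_train(n: int, interval: float, I_e: float, tau_e: float,
                   t_start: float = 0.0) -> StimulusProtocol:
    """``n`` identical pulses spaced ``interval`` seconds apart."""
    return StimulusProtocol(tuple(
        Pulse(t_start + k * interval, I_e, tau_e) for k in range(n)))


def train_with_test(n_cond: int, ipi: float, test_lag: float, I_e: float,
                    tau_e: float, t_start: float = 0.0,
                    overrides: dict[int, tuple[float | None, float | None]] | None = None,
                    ) -> StimulusProtocol:
    """Conditioning train plus one test pulse ``test_lag`` seconds after the
    last conditioning impulse.

    ``overrides`` maps pulse index to ``(I_e, tau_e)`` replacements (None
    keeps the template value).
    """
    onsets = [t_start + k * ipi for k in range(n_cond)]
    onsets.append(onsets[-1] + test_lag)
    proto = StimulusProtocol(tuple(Pulse(t, I_e, tau_e) for t in onsets))
    if overrides:
        for idx, (ie, te) in overrides.items():
            proto = proto.with_override(idx, I_e=ie, tau_e=te)
    return proto
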