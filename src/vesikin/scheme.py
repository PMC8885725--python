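"""Kinetic state chain of the vesicle fusion complex.

A pool of identical synaptic vesicles matures through a serial chain of
states — docked (``D``), preprimed (``pP``), primed (``P``) — before fusing
(``F``) and being recycled back to the docked state.  The maturation
transitions ``D ⇌ pP ⇌ P`` are bidirectional with forward rate constant
``alpha`` and backward rate constants ``beta_i = lambda_i * alpha``;
``P → F`` (fusion) and ``F → D`` (recycling, rate ``rho``) are
unidirectional.  Every forward transition, including fusion, is accelerated
by the stimulus-evoked calcium transient; backward transitions and
recycling are calcium-independent.

Chains of 3–6 states are supported: the 3-state chain drops the preprimed
state, while 5- and 6-state chains insert extra docked-like states (``D2``,
``D3``) between ``D`` and ``pP``, each with the same ``alpha``/``beta1``
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "RateParams",
    "Transition",
    "KineticScheme",
    "PoolState",
    "PropensityVector",
    "build_scheme",
    "propensities",
    "apply_transition",
    "all_docked",
]


@dataclass(frozen=True)
class RateParams:
    """Rate constants of the maturation chain.

    Parameters
    ----------
    alpha
        Forward (maturation) rate constant, s^-1.  Shared by every forward
        transition, including ``P -> F``.
    lambda1
        Dimensionless backward/forward ratio for the ``D ⇌ pP`` pair (and
        for any inserted docked-state pairs in 5/6-state chains).
    lambda2
        Same ratio for the ``pP ⇌ P`` pair.
    rho
        Recycling rate constant ``F -> D``, s^-1.
    beta1, beta2
        Backward rate constants, s^-1.  Derived as ``lambda_i * alpha``
        unless given explicitly (tabulated values that differ from the
        product after rounding take precedence).
    """

    alpha: float
    lambda1: float
    lambda2: float
    rho: float
    beta1: float = field(default=None)  # type: ignore[assignment]
    beta2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda coefficients must be non-negative")
        if self.beta1 is None:
            object.__setattr__(self, "beta1", self.lambda1 * self.alpha)
        if self.beta2 is None:
            object.__setattr__(self, "beta2", self.lambda2 * self.alpha)

    @classmethod
    def from_lambda(cls, alpha: float, lam: float, rho: float) -> "RateParams":
        """Single-λ convention: ``beta1 = beta2 = lam * alpha``."""
        return cls(alpha=alpha, lambda1=lam, lambda2=lam, rho=rho)

    @classmethod
    def from_beta(cls, alpha: float, beta: float, rho: float) -> "RateParams":
        """Single explicit β applied to every backward transition."""
        lam = beta / alpha
        return cls(alpha=alpha, lambda1=lam, lambda2=lam, rho=rho,
                   beta1=beta, beta2=beta)

    def with_rho(self, rho: float) -> "RateParams":
        return RateParams(self.alpha, self.lambda1, self.lambda2, rho,
                          self.beta1, self.beta2)


@dataclass(frozen=True)
class Transition:
    """A single kinetic transition ``source -> target``."""

    source: str
    target: str
    rate: float
    calcium_coupled: bool

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


def _state_labels(n_states: int) -> tuple[str, ...]:
    if n_states == 3:
        return ("D", "P", "F")
    inserted = tuple(f"D{i}" for i in range(2, n_states - 2))
    return ("D",) + inserted + ("pP", "P", "F")


@dataclass(frozen=True, eq=False)
class KineticScheme:
    """Immutable state chain with its transitions and change vectors.

    Transition ordering is fixed and documented so that transition indices
    in event logs are comparable across runs: forward transitions first in
    chain order (ending with ``P -> F``), then backward transitions in
    chain order, then recycling ``F -> D``.
    """

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    params: RateParams

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    @cached_property
    def fusion_index(self) -> int:
        """Index of the ``P -> F`` transition."""
        (j,) = [i for i, tr in enumerate(self.transitions) if tr.target == "F"]
        return j

    @cached_property
    def source_indices(self) -> np.ndarray:
        return np.array([self.states.index(tr.source) for tr in self.transitions],
                        dtype=np.int64)

    @cached_property
    def target_indices(self) -> np.ndarray:
        return np.array([self.states.index(tr.target) for tr in self.transitions],
                        dtype=np.int64)

    @cached_property
    def base_rates(self) -> np.ndarray:
        return np.array([tr.rate for tr in self.transitions], dtype=np.float64)

    @cached_property
    def coupled_mask(self) -> np.ndarray:
        return np.array([tr.calcium_coupled for tr in self.transitions], dtype=np.bool_)

    @cached_property
    def change_vectors(self) -> np.ndarray:
        """``(n_transitions, n_states)`` array; row j decrements the source
        of transition j and increments its target."""
        v = np.zeros((self.n_transitions, self.n_states), dtype=np.int64)
        v[np.arange(self.n_transitions), self.source_indices] -= 1
        v[np.arange(self.n_transitions), self.target_indices] += 1
        return v

    def labels(self) -> list[str]:
        return [tr.label for tr in self.transitions]


def build_scheme(n_states: int, params: RateParams) -> KineticScheme:
    """Assemble the maturation chain for 3 to 6 states.

    The 4-state chain has 6 transitions; removing the preprimed state gives
    4; every inserted docked-like state adds a bidirectional pair.  Inserted
    pairs reuse ``alpha``/``beta1``; the pair adjacent to ``P`` uses
    ``beta2``.
    """
    if n_states not in (3, 4, 5, 6):
        raise ValueError(f"n_states must be in 3..6, got {n_states}")
    states = _state_labels(n_states)
    chain = states[:-1]  # maturation chain, ends at P
    forward = [
        Transition(chain[i], chain[i + 1], params.alpha, True)
        for i in range(len(chain) - 1)
    ]
    forward.append(Transition("P", "F", params.alpha, True))
    backward = []
    for i in range(len(chain) - 1):
        beta = params.beta2 if chain[i + 1] == "P" else params.beta1
        backward.append(Transition(chain[i + 1], chain[i], beta, False))
    recycling = [Transition("F", "D", params.rho, False)]
    return KineticScheme(states=states,
                         transitions=tuple(forward + backward + recycling),
                         params=params)


@dataclass
class PoolState:
    """Integer occupancy of the vesicle pool at a moment in time."""

    counts: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"negative state count: {self.counts}")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "PoolState":
        return PoolState(self.counts.copy(), self.t)


def all_docked(scheme: KineticScheme, n_total: int, t: float = 0.0) -> PoolState:
    """Initial condition: every vesicle in the docked state."""
    counts = np.zeros(scheme.n_states, dtype=np.int64)
    counts[0] = n_total
    return PoolState(counts, t)


@dataclass(frozen=True)
class PropensityVector:
    """Per-transition propensities a_j (s^-1) and their total a0."""

    a: np.ndarray
    a0: float
    evaluated_at: float = 0.0


def propensities(scheme: KineticScheme, state: PoolState,
                 f_value: float = 0.0) -> PropensityVector:
    """Propensity of each transition: (rate + f for calcium-coupled ones)
    times the source-state count.

    ``f_value`` is the instantaneous calcium-transient increment in s^-1;
    it adds to the rate constant of every calcium-coupled transition.
    """
    if f_value < 0:
        raise ValueError("f_value must be non-negative")
    if (state.counts < 0).any():
        raise RuntimeError(f"negative count in pool state: {state.counts}")
    rates = scheme.base_rates + f_value * scheme.coupled_mask
    a = rates * state.counts[scheme.source_indices]
    return PropensityVector(a=a, a0=float(a.sum()), evaluated_at=state.t)


def apply_transition(state: PoolState, scheme: KineticScheme, j: int) -> PoolState:
    """Apply transition ``j``; conservation of the pool total is automatic."""
    if not 0 <= j < scheme.n_transitions:
        raise IndexError(f"transition index {j} out of range")
    if state.counts[scheme.source_indices[j]] < 1:
        raise ValueError(
            f"transition {scheme.transitions[j].label} has empty source state")
    return PoolState(state.counts + scheme.change_vectors[j], state.t)
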