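"""Small-mutation (mu -> 0) limits for the two-type Moran process.

For the classical constant-fitness Moran process (type A with relative
fitness ``r``, type B with fitness 1) the fixation probabilities of a
single mutant are the textbook closed forms

    rho_A = (1 - r^-1) / (1 - r^-N),     rho_B = (1 - r) / (1 - r^N),

with the continuity value ``1/N`` for both at ``r = 1``. As the mutation
rate vanishes the stationary distribution concentrates on the two corner
states in proportion to the fixation probabilities (the embedded two-state
chain jumps corner-to-corner at rates ``mu * rho``), and the ratio of the
corner RTEs converges to

    lim H_(0,N) / H_(N,0) = s(N,0) / s(0,N) = rho_A / rho_B = r^(N-1),

so the type with the greater fixation probability occupies the more stable
corner. The entropy rate itself vanishes in the limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixationPair",
    "moran_fixation",
    "small_mutation_stationary",
    "limiting_rte_ratio",
]

# Below this distance from r = 1 the closed forms lose all precision to
# cancellation; route to the neutral limit 1/N instead.
_NEUTRAL_WINDOW = 1e-10


@dataclass(frozen=True)
class FixationPair:
    """Fixation probabilities of a single A mutant among B residents
    (``rho_A``) and a single B mutant among A residents (``rho_B``), for
    relative fitness ``r`` of A in a population of size ``N``."""

    rho_A: float
    rho_B: float
    r: float
    N: int

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_A <= 1.0 and 0.0 < self.rho_B <= 1.0):
            raise ValueError("fixation probabilities must lie in (0, 1]")


def moran_fixation(r: float, N: int) -> FixationPair:
    """Classical Moran fixation probabilities for both types.

    ``r`` is the relative fitness of type A; ``N >= 2`` the population
    size. At ``r = 1`` (or within cancellation distance of it) both types
    fix with the neutral probability ``1/N``.
    """
    if r <= 0.0:
        raise ValueError("relative fitness r must be positive")
    if N < 2:
        raise ValueError("population size N must be >= 2")
    if abs(r - 1.0) < _NEUTRAL_WINDOW:
        return FixationPair(1.0 / N, 1.0 / N, r, N)
    with np.errstate(over="ignore"):
        rho_a = (1.0 - 1.0 / r) / (1.0 - float(np.power(r, -float(N))))
        rho_b = (1.0 - r) / (1.0 - float(np.power(r, float(N))))
    return FixationPair(float(rho_a), float(rho_b), r, N)


def small_mutation_stationary(fix: FixationPair) -> dict[tuple[int, int], float]:
    """The mu -> 0 limiting stationary distribution: a two-point mass on the
    corner states, ``s(N,0) = rho_A / (rho_A + rho_B)`` and
    ``s(0,N) = rho_B / (rho_A + rho_B)`` (states as (count of A, count of B))."""
    total = fix.rho_A + fix.rho_B
    return {
        (fix.N, 0): fix.rho_A / total,
        (0, fix.N): fix.rho_B / total,
    }


def limiting_rte_ratio(r: float, N: int) -> float:
    """The mu -> 0 limit of the corner RTE ratio ``H_(0,N) / H_(N,0)``.

    Equals ``rho_A / rho_B``, which simplifies exactly to ``r**(N-1)``;
    returns 1 at ``r = 1`` by continuity. A value above 1 means the all-A
    corner is the more stable equilibrium (iff ``r > 1``).
    """
    if r <= 0.0:
        raise ValueError("relative fitness r must be positive")
    if N < 2:
        raise ValueError("population size N must be >= 2")
    if abs(r - 1.0) < _NEUTRAL_WINDOW:
        return 1.0
    with np.errstate(over="ignore"):
        return float(np.power(r, float(N - 1)))
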