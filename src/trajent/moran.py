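"""The Moran process with mutation on the simplex lattice.

A population of ``N`` individuals of ``n`` types lives on the discrete
simplex of count vectors ``a = (a_1, ..., a_n)`` with ``sum a_i = N``. Each
step one individual reproduces — fitness-proportionately, with mutation of
the offspring — and one dies uniformly at random, giving the birth–death
transition probabilities

    T(a -> a + i_{u,w}) = p_u(abar) * abar_w        (u != w),

where ``abar = a / N``, ``i_{u,w}`` adds one ``u`` and removes one ``w``,
and ``p(abar) = phi(abar) M / sum phi`` combines the selection weights
``phi`` with the mutation matrix ``M``. Two selection kernels are provided:
linear (``phi_i = abar_i f_i``) and Fermi (``phi_i = abar_i exp(beta f_i)``)
with fitness ``f = G abar`` from a game payoff matrix ``G``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .markov import FiniteMarkovProcess, ROW_SUM_TOL

__all__ = [
    "GameLandscape",
    "MutationModel",
    "enumerate_states",
    "n_simplex_states",
    "selection_weights",
    "reproduction_distribution",
    "uniform_mutation_matrix",
    "build_moran_chain",
    "hawk_dove_matrix",
    "three_type_matrix",
    "rps_matrix",
    "classical_matrix",
    "load_payoff_matrix",
    "resolve_payoff",
    "PRESETS",
]

KERNELS = ("linear", "fermi")

# Exponent shift threshold for the Fermi kernel; beyond this the weights are
# rescaled by exp(-max beta*f), which leaves the normalized reproduction
# distribution unchanged.
_FERMI_SAFE_EXPONENT = 600.0


@dataclass(frozen=True)
class GameLandscape:
    """A fitness landscape ``f(abar) = G abar`` with a selection kernel.

    Parameters
    ----------
    payoff
        Square ``n x n`` game matrix ``G`` (``n >= 2``).
    beta
        Selection intensity (Fermi kernel only); ``beta = 0`` is neutral.
    kernel
        ``"linear"`` (``phi_i = abar_i f_i``, requires positive fitness) or
        ``"fermi"`` (``phi_i = abar_i exp(beta f_i)``).
    """

    payoff: np.ndarray
    beta: float = 0.0
    kernel: str = "fermi"

    def __post_init__(self) -> None:
        G = np.asarray(self.payoff, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1] or G.shape[0] < 2:
            raise ValueError("payoff must be a square matrix with n >= 2")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.beta < 0:
            raise ValueError("selection intensity beta must be nonnegative")
        object.__setattr__(self, "payoff", G)

    @property
    def n_types(self) -> int:
        return self.payoff.shape[0]

    def fitness(self, xbar: np.ndarray) -> np.ndarray:
        """Per-type fitness ``f(abar) = G abar``."""
        return self.payoff @ np.asarray(xbar, dtype=float)


@dataclass(frozen=True)
class MutationModel:
    """A row-stochastic mutation matrix ``M``; ``M_ij`` is the probability
    that an offspring of type ``i`` is born as type ``j``."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("mutation matrix must be square")
        if (M < -1e-15).any() or (M > 1 + 1e-12).any():
            raise ValueError("mutation probabilities must lie in [0, 1]")
        if np.abs(M.sum(axis=1) - 1.0).max() > ROW_SUM_TOL:
            raise ValueError("mutation matrix rows must sum to 1")
        object.__setattr__(self, "matrix", M)

    @property
    def n_types(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def uniform(cls, n: int, mu: float) -> "MutationModel":
        return uniform_mutation_matrix(n, mu)


def uniform_mutation_matrix(n: int, mu: float) -> MutationModel:
    """The symmetric mutation model: offspring keep their parent's type
    with probability ``1 - mu`` and mutate to each of the other ``n - 1``
    types with probability ``mu / (n - 1)``."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation rate mu must lie in [0, 1]")
    if n < 2:
        raise ValueError("need at least two types")
    M = np.full((n, n), mu / (n - 1))
    np.fill_diagonal(M, 1.0 - mu)
    return MutationModel(M)


def enumerate_states(N: int, n: int) -> list[tuple[int, ...]]:
    """All population states: integer compositions of ``N`` into ``n``
    nonnegative parts, in ascending lexicographic order. There are
    ``C(N + n - 1, n - 1)`` of them."""
    if N < 1:
        raise ValueError("population size N must be >= 1")
    if n < 2:
        raise ValueError("need at least two types")

    out: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int, parts: int) -> None:
        if parts == 1:
            out.append(prefix + (remaining,))
            return
        for a in range(remaining + 1):
            rec(prefix + (a,), remaining - a, parts - 1)

    rec((), N, n)
    return out


def n_simplex_states(N: int, n: int) -> int:
    """Number of lattice points of the ``n``-type simplex at size ``N``:
    ``C(N + n - 1, n - 1)``."""
    return math.comb(N + n - 1, n - 1)


def selection_weights(state: Sequence[int], landscape: GameLandscape) -> np.ndarray:
    """Unnormalized selection weights ``phi(abar)`` at a population state.

    Linear kernel: ``phi_i = abar_i * f_i(abar)``; every present type must
    have positive fitness. Fermi kernel: ``phi_i = abar_i * exp(beta * f_i)``
    (rescaled by a common factor only when the exponent would overflow,
    which cancels in the reproduction distribution).
    """
    a = np.asarray(state, dtype=float)
    if a.shape != (landscape.n_types,):
        raise ValueError(
            f"state has {a.shape} entries, landscape expects {landscape.n_types}"
        )
    N = a.sum()
    if N <= 0:
        raise ValueError("state must contain at least one individual")
    xbar = a / N
    f = landscape.fitness(xbar)
    present = xbar > 0.0
    if landscape.kernel == "linear":
        if (f[present] <= 0.0).any():
            raise ValueError(
                "linear selection kernel requires positive fitness for every present type"
            )
        return xbar * f
    expo = landscape.beta * f
    shift = float(expo[present].max())
    if shift <= _FERMI_SAFE_EXPONENT:
        shift = 0.0
    with np.errstate(over="ignore"):
        phi = np.where(present, xbar * np.exp(expo - shift), 0.0)
    return phi


def reproduction_distribution(phi: np.ndarray, mutation: MutationModel) -> np.ndarray:
    """Probability that the next newborn is of each type:
    ``p_i = sum_k phi_k M_ki / sum_k phi_k``."""
    phi = np.asarray(phi, dtype=float)
    total = float(phi.sum())
    if total <= 0.0:
        raise ValueError("selection weights must have positive total")
    if (phi < 0).any():
        raise ValueError("selection weights must be nonnegative")
    return (phi @ mutation.matrix) / total


def build_moran_chain(
    N: int,
    landscape: GameLandscape,
    mutation: MutationModel,
    *,
    mutation_fn: Callable[[tuple[int, ...]], MutationModel] | None = None,
) -> FiniteMarkovProcess:
    """Assemble the full Moran chain on the simplex lattice.

    ``mutation_fn`` optionally supplies a state-dependent mutation matrix
    (``mutation`` is then ignored per state); the shipped construction is
    the constant uniform matrix.

    With ``mu = 0`` the corner states are absorbing and the chain is not
    irreducible; it can still be built (for fixation studies) but the
    stationary and entropy machinery will reject it.
    """
    n = landscape.n_types
    if mutation_fn is None and mutation.n_types != n:
        raise ValueError("mutation and landscape type counts differ")
    states = enumerate_states(N, n)
    pairs = [(u, w) for u in range(n) for w in range(n) if u != w]
    transitions: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    for a in states:
        M = mutation_fn(a) if mutation_fn is not None else mutation
        phi = selection_weights(a, landscape)
        p = reproduction_distribution(phi, M)
        xbar = np.asarray(a, dtype=float) / N
        off_total = 0.0
        for u, w in pairs:
            tp = p[u] * xbar[w]
            if tp > 0.0:
                target = list(a)
                target[u] += 1
                target[w] -= 1
                transitions[(a, tuple(target))] = float(tp)
                off_total += tp
        diag = 1.0 - off_total
        if diag > 0.0:
            transitions[(a, a)] = diag
    return FiniteMarkovProcess(states, transitions)


# -- payoff matrix presets and I/O --------------------------------------------


def hawk_dove_matrix() -> np.ndarray:
    """Two-type Hawk–Dove game favoring the mixed half-and-half state."""
    return np.array([[1.0, 2.0], [2.0, 1.0]])


def three_type_matrix() -> np.ndarray:
    """Fully symmetric three-type coordination-style game (zero diagonal,
    unit off-diagonal) with extrema at corners, edge midpoints, and the
    simplex center."""
    return np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])


def rps_matrix() -> np.ndarray:
    """Zero-sum rock–paper–scissors game with cyclic dominance."""
    return np.array([[0.0, 1.0, -1.0], [-1.0, 0.0, 1.0], [1.0, -1.0, 0.0]])


def classical_matrix(r: float) -> np.ndarray:
    """Constant-fitness two-type game: type A has relative fitness ``r``,
    type B fitness 1, for any population composition."""
    if r <= 0:
        raise ValueError("relative fitness r must be positive")
    return np.array([[r, r], [1.0, 1.0]])


PRESETS: dict[str, Callable[[], np.ndarray]] = {
    "hawkdove": hawk_dove_matrix,
    "threetype": three_type_matrix,
    "rps": rps_matrix,
}


def load_payoff_matrix(path: str | Path) -> np.ndarray:
    """Read a payoff matrix from delimited text: ``n`` rows of ``n``
    whitespace- or comma-separated numbers."""
    text = Path(path).read_text(encoding="utf-8")
    rows = [
        [float(x) for x in line.replace(",", " ").split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    G = np.array(rows, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError(f"payoff file {path} is not a square matrix")
    return G


def resolve_payoff(name_or_path: str) -> np.ndarray:
    """Resolve a payoff specification: a preset name (``hawkdove``,
    ``threetype``, ``rps``, ``classical:<r>``) or a path to a matrix file."""
    if name_or_path in PRESETS:
        return PRESETS[name_or_path]()
    if name_or_path.startswith("classical:"):
        return classical_matrix(float(name_or_path.split(":", 1)[1]))
    return load_payoff_matrix(name_or_path)
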