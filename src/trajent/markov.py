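"""Finite Markov chains and trajectory-entropy primitives.

This module provides the chain container (:class:`FiniteMarkovProcess`), the
entropy rate of a stationary chain, probabilities and explicit enumeration of
first-return trajectories, and two routes to the random trajectory entropy
(RTE) of a state:

* the closed form ``H_v = H(X) / s(v)`` — entropy rate over stationary
  probability (:func:`rte`);
* an exhaustive truncated sum over all first-return paths up to a length
  horizon (:func:`rte_brute_force`), which serves as an independent oracle
  for the closed form.

All entropies are in nats (natural logarithm); the base can be changed
globally through :data:`LOG_BASE`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LOG_BASE",
    "ROW_SUM_TOL",
    "FiniteMarkovProcess",
    "Trajectory",
    "TruncatedRTE",
    "entropy_rate",
    "trajectory_probability",
    "enumerate_first_return_trajectories",
    "rte_brute_force",
    "rte",
    "make_fixture_chain",
    "format_state",
    "parse_state",
]

#: Base of all logarithms. ``math.e`` gives entropies in nats.
LOG_BASE: float = math.e

#: Tolerance for row-stochasticity of transition matrices.
ROW_SUM_TOL: float = 1e-12

# Chains at or below this size use dense arrays internally (faster matvecs).
_DENSE_LIMIT = 2048


def _log(x: float) -> float:
    return math.log(x, LOG_BASE) if LOG_BASE != math.e else math.log(x)


def _log_array(a: np.ndarray) -> np.ndarray:
    out = np.log(a)
    if LOG_BASE != math.e:
        out /= math.log(LOG_BASE)
    return out


class ChainStructureError(ValueError):
    """Raised when a transition table violates a structural requirement."""


class NotIrreducibleError(ChainStructureError):
    """Raised when an operation requires an irreducible chain but the
    transition graph is not strongly connected."""


def format_state(state: Hashable) -> str:
    """Serialize a state label: count tuples become comma-joined integers
    (``(15, 15)`` -> ``"15,15"``), anything else uses ``str``."""
    if isinstance(state, tuple):
        return ",".join(str(c) for c in state)
    return str(state)


def parse_state(text: str) -> Hashable:
    """Inverse of :func:`format_state` for integer and count-tuple labels."""
    text = text.strip()
    if "," in text:
        return tuple(int(part) for part in text.split(","))
    try:
        return int(text)
    except ValueError:
        return text


class FiniteMarkovProcess:
    """A finite Markov chain as an ordered state list plus a sparse
    row-stochastic transition matrix.

    Parameters
    ----------
    states
        Hashable state labels. They are sorted lexicographically (when
        mutually orderable) so that indexing and serialization are
        deterministic.
    transitions
        Either a mapping ``(u, v) -> probability`` or a 2-d array aligned
        with the *given* order of ``states`` (it is re-indexed if sorting
        permutes the states).
    validate
        When true (default), verify probabilities lie in [0, 1] and every
        row sums to one within :data:`ROW_SUM_TOL`.
    """

    def __init__(
        self,
        states: Iterable[Hashable],
        transitions: Mapping[tuple[Hashable, Hashable], float] | np.ndarray | sparse.spmatrix,
        *,
        validate: bool = True,
    ) -> None:
        given = list(states)
        if len(given) == 0:
            raise ChainStructureError("a chain needs at least one state")
        if len(set(given)) != len(given):
            raise ChainStructureError("duplicate state labels")
        try:
            ordered = sorted(given)
        except TypeError:
            ordered = given
        self._states: tuple[Hashable, ...] = tuple(ordered)
        self._index: dict[Hashable, int] = {s: i for i, s in enumerate(self._states)}
        n = len(self._states)

        if isinstance(transitions, Mapping):
            rows, cols, data = [], [], []
            for (u, v), p in transitions.items():
                if u not in self._index or v not in self._index:
                    raise ChainStructureError(f"transition references unknown state: {(u, v)}")
                if p != 0.0:
                    rows.append(self._index[u])
                    cols.append(self._index[v])
                    data.append(float(p))
            mat = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        else:
            arr = transitions.toarray() if sparse.issparse(transitions) else np.asarray(transitions, dtype=float)
            if arr.shape != (n, n):
                raise ChainStructureError(f"transition matrix shape {arr.shape} != ({n}, {n})")
            perm = np.array([given.index(s) for s in self._states])
            mat = sparse.csr_matrix(arr[np.ix_(perm, perm)])
        mat.sum_duplicates()
        self._T = mat
        self._dense: np.ndarray | None = None
        self._irreducible: bool | None = None
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        data = self._T.data
        if data.size and (data.min() < -1e-15 or data.max() > 1.0 + 1e-12):
            raise ChainStructureError("transition probabilities must lie in [0, 1]")
        rowsums = np.asarray(self._T.sum(axis=1)).ravel()
        bad = np.abs(rowsums - 1.0) > ROW_SUM_TOL
        if bad.any():
            i = int(np.argmax(bad))
            raise ChainStructureError(
                f"row for state {self._states[i]!r} sums to {rowsums[i]!r}, not 1"
            )

    # -- basic accessors ------------------------------------------------------

    @property
    def states(self) -> tuple[Hashable, ...]:
        return self._states

    @property
    def n_states(self) -> int:
        return len(self._states)

    @property
    def matrix(self) -> sparse.csr_matrix:
        """The row-stochastic transition matrix in CSR form."""
        return self._T

    def todense(self) -> np.ndarray:
        if self._dense is None:
            self._dense = self._T.toarray()
        return self._dense

    def index(self, state: Hashable) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise KeyError(f"unknown state: {state!r}") from None

    def prob(self, u: Hashable, v: Hashable) -> float:
        """Transition probability T(u, v)."""
        return float(self._T[self.index(u), self.index(v)])

    def row(self, state: Hashable) -> dict[Hashable, float]:
        """Successors of ``state`` with their probabilities."""
        i = self.index(state)
        start, stop = self._T.indptr[i], self._T.indptr[i + 1]
        return {
            self._states[j]: float(p)
            for j, p in zip(self._T.indices[start:stop], self._T.data[start:stop])
        }

    @property
    def is_irreducible(self) -> bool:
        """Whether the support graph is strongly connected."""
        if self._irreducible is None:
            ncomp, _ = connected_components(self._T, directed=True, connection="strong")
            self._irreducible = ncomp == 1
        return self._irreducible

    def require_irreducible(self) -> None:
        if not self.is_irreducible:
            raise NotIrreducibleError(
                "chain is not irreducible (transition graph not strongly connected); "
                "for mutation-free population chains use the fixation module instead"
            )

    # -- serialization --------------------------------------------------------

    def to_edgelist(self, path: str | Path | None = None) -> str:
        """Serialize as a delimited edge list: ``from<TAB>to<TAB>probability``,
        one positive edge per line, states formatted by :func:`format_state`."""
        lines = []
        coo = self._T.tocoo()
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            u, v, p = self._states[coo.row[k]], self._states[coo.col[k]], coo.data[k]
            lines.append(f"{format_state(u)}\t{format_state(v)}\t{float(p)!r}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_edgelist(cls, source: str | Path) -> "FiniteMarkovProcess":
        """Parse a chain from the edge-list format of :meth:`to_edgelist`.

        ``source`` is a path if it names an existing file, otherwise it is
        treated as the edge-list text itself.
        """
        p = Path(source) if not isinstance(source, Path) else source
        try:
            is_file = p.is_file()
        except OSError:
            is_file = False
        text = p.read_text(encoding="utf-8") if is_file else str(source)
        transitions: dict[tuple[Hashable, Hashable], float] = {}
        states: set[Hashable] = set()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u_s, v_s, p_s = line.split("\t")
            u, v = parse_state(u_s), parse_state(v_s)
            states.update((u, v))
            transitions[(u, v)] = float(p_s)
        return cls(states, transitions)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FiniteMarkovProcess(n_states={self.n_states}, nnz={self._T.nnz})"


@dataclass(frozen=True)
class Trajectory:
    """A path of at least two states with its probability (the product of
    the step transition probabilities along the path)."""

    path: tuple[Hashable, ...]
    probability: float

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValueError("a trajectory needs at least two states")

    @property
    def origin(self) -> Hashable:
        return self.path[0]

    @property
    def terminal(self) -> Hashable:
        return self.path[-1]

    @property
    def is_first_return(self) -> bool:
        """True when origin equals terminal and no intermediate step visits
        the terminal state."""
        return self.path[0] == self.path[-1] and self.path[-1] not in self.path[1:-1]


@dataclass(frozen=True)
class TruncatedRTE:
    """Result of the truncated first-return entropy sum.

    Attributes
    ----------
    entropy
        ``-sum p log p`` over all first-return paths up to the horizon.
    mass
        Total probability of the summed paths; approaches 1 as the horizon
        grows (irreducible chains).
    tail_bound
        A rigorous upper bound on the entropy contribution of the paths
        beyond the horizon (``inf`` if no geometric return bound exists).
    """

    entropy: float
    mass: float
    tail_bound: float


def _stationary_as_array(process: FiniteMarkovProcess, stationary) -> np.ndarray:
    if hasattr(stationary, "as_array"):
        s = stationary.as_array(process.states)
    elif isinstance(stationary, Mapping):
        missing = [v for v in process.states if v not in stationary]
        if missing:
            raise ValueError(f"stationary distribution missing states: {missing[:3]}")
        s = np.array([float(stationary[v]) for v in process.states])
    else:
        s = np.asarray(stationary, dtype=float)
    if s.shape != (process.n_states,):
        raise ValueError(
            f"stationary vector length {s.shape} does not match {process.n_states} states"
        )
    return s


def entropy_rate(process: FiniteMarkovProcess, stationary, *, norm_tol: float = 1e-8) -> float:
    """Entropy rate ``H(X) = -sum_{i,j} s(v_i) T(v_i,v_j) log T(v_i,v_j)``
    of a stationary chain, in nats per step, with ``0 log 0 := 0``.

    ``stationary`` may be a mapping state -> probability, an array aligned
    with ``process.states``, or a ``StationaryResult``.
    """
    s = _stationary_as_array(process, stationary)
    if (s < -1e-15).any():
        raise ValueError("stationary probabilities must be nonnegative")
    if abs(float(s.sum()) - 1.0) > norm_tol:
        raise ValueError(f"stationary vector sums to {s.sum()!r}, not 1")
    T = process.matrix
    data = T.data
    plogp = np.zeros_like(data)
    pos = data > 0.0
    plogp[pos] = data[pos] * _log_array(data[pos])
    row_h = np.zeros(process.n_states)
    np.add.at(row_h, np.repeat(np.arange(process.n_states), np.diff(T.indptr)), plogp)
    h = -float(s @ row_h)
    return max(h, 0.0)


def trajectory_probability(process: FiniteMarkovProcess, path) -> float:
    """Probability of a path: the product of transitions along consecutive
    pairs. Returns 0 as soon as any step is forbidden."""
    seq: Sequence[Hashable] = path.path if isinstance(path, Trajectory) else tuple(path)
    if len(seq) < 2:
        raise ValueError("a trajectory needs at least two states")
    prob = 1.0
    for u, v in zip(seq[:-1], seq[1:]):
        p = process.prob(u, v)
        if p == 0.0:
            return 0.0
        prob *= p
    return prob


def enumerate_first_return_trajectories(
    process: FiniteMarkovProcess,
    v: Hashable,
    max_len: int,
    *,
    prob_floor: float = 1e-15,
) -> list[Trajectory]:
    """All first-return trajectories from ``v`` back to ``v`` of at most
    ``max_len`` steps, with their probabilities.

    Branches whose prefix probability falls below ``prob_floor`` are pruned
    (set ``prob_floor=0`` for exact enumeration). Paths are returned in
    depth-first lexicographic order of state indices.
    """
    o = process.index(v)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    T = process.matrix
    states = process.states

    def successors(i: int) -> list[tuple[int, float]]:
        start, stop = T.indptr[i], T.indptr[i + 1]
        pairs = sorted(zip(T.indices[start:stop], T.data[start:stop]))
        return [(int(j), float(p)) for j, p in pairs if p > 0.0]

    out: list[Trajectory] = []
    # Iterative DFS; stack entries are (state index, path indices, prefix prob).
    stack: list[tuple[int, tuple[int, ...], float]] = [(o, (o,), 1.0)]
    while stack:
        i, path, prob = stack.pop()
        steps_taken = len(path) - 1
        for j, p in reversed(successors(i)):
            q = prob * p
            if prob_floor > 0.0 and q < prob_floor:
                continue
            if j == o:
                out.append(Trajectory(tuple(states[k] for k in path) + (v,), q))
            elif steps_taken + 1 < max_len:
                stack.append((j, path + (j,), q))
    out.sort(key=lambda t: (len(t.path), tuple(process.index(x) for x in t.path)))
    return out


def rte_brute_force(process: FiniteMarkovProcess, v: Hashable, max_len: int) -> TruncatedRTE:
    """Truncated random trajectory entropy of state ``v`` by exhaustive
    summation over every first-return path of at most ``max_len`` steps.

    The sum ``-sum_V Pr(V) log Pr(V)`` is accumulated exactly (all paths,
    no pruning) by propagating, per path length, the total mass and the
    ``p log p`` aggregate of path prefixes that have not yet revisited
    ``v``; this is algebraically identical to enumerating each path. As
    ``max_len`` grows the captured mass tends to 1 and the entropy to the
    closed-form value ``H(X)/s(v)``.
    """
    process.require_irreducible()
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    o = process.index(v)
    T = process.todense()
    n = process.n_states
    with np.errstate(divide="ignore"):
        logT = np.where(T > 0.0, _log_array(np.where(T > 0.0, T, 1.0)), 0.0)
    TlogT = T * logT

    m = np.zeros(n)
    m[o] = 1.0
    plp = np.zeros(n)  # sum of p*log(p) over prefixes ending at each state
    entropy = 0.0
    mass = 0.0
    for _ in range(max_len):
        m2 = m @ T
        plp2 = plp @ T + m @ TlogT
        mass += m2[o]
        entropy -= plp2[o]
        m2[o] = 0.0
        plp2[o] = 0.0
        m, plp = m2, plp2
        if m.sum() < 1e-300:
            break

    residual = max(0.0, 1.0 - mass)
    tail_bound = _tail_entropy_bound(process, o, max_len, residual)
    return TruncatedRTE(entropy=float(entropy), mass=float(mass), tail_bound=tail_bound)


def _tail_entropy_bound(
    process: FiniteMarkovProcess, o: int, max_len: int, residual: float
) -> float:
    """Upper bound on the entropy of first-return paths longer than
    ``max_len``.

    Every such path of length L has probability at least ``t_min**L`` (each
    step uses a positive transition), so its ``-p log p`` is at most
    ``p * L * (-log t_min)``; the mass at length L decays at least
    geometrically with ratio ``lam = max_{x != v} (1 - T(x, v))``.
    """
    if residual <= 0.0:
        return 0.0
    T = process.todense()
    t_min = float(T[T > 0.0].min())
    col = np.delete(T[:, o], o)
    lam = float(np.max(1.0 - col)) if col.size else 0.0
    if lam >= 1.0:
        return math.inf
    log_inv = -_log(t_min)
    L = max_len + 1
    return residual * log_inv * (L / (1.0 - lam) + lam / (1.0 - lam) ** 2)


def rte(entropy_rate: float, stationary_prob: float) -> float:
    """Random trajectory entropy of a state via the closed form
    ``H_v = H(X) / s(v)`` (nats)."""
    if stationary_prob <= 0.0:
        raise ValueError("stationary probability must be positive")
    if entropy_rate < 0.0:
        raise ValueError("entropy rate must be nonnegative")
    return entropy_rate / stationary_prob


def make_fixture_chain(n_states: int, seed: int) -> FiniteMarkovProcess:
    """A seeded, strictly positive (hence irreducible and aperiodic)
    row-stochastic chain on integer states ``0..n_states-1``, for oracle
    testing."""
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.1, 1.0, size=(n_states, n_states))
    raw /= raw.sum(axis=1, keepdims=True)
    # Renormalize exactly so rows pass the 1e-12 stochasticity check.
    raw[:, -1] = 1.0 - raw[:, :-1].sum(axis=1)
    return FiniteMarkovProcess(range(n_states), raw)
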