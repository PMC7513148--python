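"""Stationary distributions of irreducible finite chains.

Two solvers: sparse power iteration (the general route) and an exact
product-form solver for birth–death (tridiagonal) chains such as the
two-type Moran process, where detailed balance gives

    s_k  proportional to  prod_{j < k} T(j -> j+1) / T(j+1 -> j).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterator, Mapping

import numpy as np

from .markov import FiniteMarkovProcess, format_state

__all__ = [
    "StationaryResult",
    "ConvergenceError",
    "stationary_power_iteration",
    "stationary_birth_death_exact",
    "solve_stationary",
]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested residual."""


@dataclass(frozen=True)
class StationaryResult(Mapping):
    """A stationary distribution with solver metadata.

    Behaves as a read-only mapping ``state -> probability``. ``residual`` is
    the L1 norm of ``sT - s`` at termination and ``iterations`` the number of
    matrix–vector products performed (0 for the exact solver).
    """

    states: tuple[Hashable, ...]
    probabilities: np.ndarray
    method: str
    residual: float
    iterations: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, dtype=float))
        if len(self.states) != self.probabilities.shape[0]:
            raise ValueError("states and probabilities length mismatch")

    # Mapping interface -------------------------------------------------------

    def __getitem__(self, state: Hashable) -> float:
        if not hasattr(self, "_index"):
            object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.states)})
        try:
            return float(self.probabilities[self._index[state]])
        except KeyError:
            raise KeyError(state) from None

    def __iter__(self) -> Iterator[Hashable]:
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    # Convenience -------------------------------------------------------------

    def as_array(self, states: tuple[Hashable, ...] | None = None) -> np.ndarray:
        """Probabilities aligned with ``states`` (default: own order)."""
        if states is None or tuple(states) == self.states:
            return self.probabilities
        idx = {s: i for i, s in enumerate(self.states)}
        return self.probabilities[[idx[s] for s in states]]

    def as_dict(self) -> dict[Hashable, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}

    @property
    def argmax(self) -> Hashable:
        return self.states[int(np.argmax(self.probabilities))]

    @property
    def argmin(self) -> Hashable:
        return self.states[int(np.argmin(self.probabilities))]

    def to_csv(self, path: str | Path | None = None) -> str:
        """Export as ``state,probability`` CSV, states in chain order."""
        lines = ["state,probability"] + [
            f"{format_state(s)},{float(p)!r}"
            for s, p in zip(self.states, self.probabilities)
        ]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def stationary_power_iteration(
    process: FiniteMarkovProcess,
    *,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> StationaryResult:
    """Left power iteration ``s <- sT`` from the uniform vector until the
    L1 residual ``||sT - s||_1`` drops below ``tol``.

    Requires an irreducible chain (verified by strong connectivity of the
    support graph). Deterministic given its inputs.
    """
    process.require_irreducible()
    n = process.n_states
    T = process.todense() if n <= 2048 else process.matrix
    s = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        nxt = s @ T
        nxt = np.asarray(nxt).ravel()
        resid = float(np.abs(nxt - s).sum())
        if resid <= tol:
            s = nxt / nxt.sum()
            return StationaryResult(process.states, s, "power_iteration", resid, it)
        s = nxt / nxt.sum()
    raise ConvergenceError(
        f"power iteration did not reach L1 residual {tol} in {max_iter} iterations "
        f"(last residual {resid})"
    )


def stationary_birth_death_exact(process: FiniteMarkovProcess) -> StationaryResult:
    """Exact stationary distribution for a birth–death chain: the transition
    matrix must be tridiagonal in the chain's state order with positive
    up/down rates between consecutive states.

    The product form satisfies detailed balance
    ``s_j T(j, j+1) = s_{j+1} T(j+1, j)`` exactly; the products are
    accumulated in log space for numerical range.
    """
    T = process.todense()
    n = process.n_states
    band = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) <= 1
    if (T[~band] != 0.0).any():
        raise ValueError("chain is not tridiagonal in its state ordering")
    up = np.diag(T, k=1)
    down = np.diag(T, k=-1)
    if (up <= 0.0).any() or (down <= 0.0).any():
        raise ValueError("birth–death solver needs positive up/down rates everywhere")
    log_s = np.concatenate(([0.0], np.cumsum(np.log(up) - np.log(down))))
    log_s -= log_s.max()
    s = np.exp(log_s)
    s /= s.sum()
    resid = float(np.abs(s @ T - s).sum())
    return StationaryResult(process.states, s, "birth_death_exact", resid, 0)


def solve_stationary(
    process: FiniteMarkovProcess,
    method: str = "power",
    **kwargs,
) -> StationaryResult:
    """Dispatch to a stationary solver: ``"power"`` or ``"exact"``."""
    if method == "power":
        return stationary_power_iteration(process, **kwargs)
    if method == "exact":
        return stationary_birth_death_exact(process, **kwargs)
    raise ValueError(f"unknown method {method!r}")
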