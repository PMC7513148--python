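"""Parameter sweeps over selection intensity, mutation rate, and
population size, plus permutation-symmetry checks of the stationary
distribution.

Sweep output is a long-format :class:`pandas.DataFrame` with one row per
(parameter value, tracked state): entropy rate, stationary probability,
RTE, and RTE normalized by the state count ``C(N+n-1, n-1)`` (the fair
comparison across population sizes, where state spaces differ)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .markov import format_state
from .model import MoranModel
from .moran import n_simplex_states

__all__ = ["tracked_states", "run_sweep", "symmetry_check", "SweepError"]

SWEEPABLE = ("beta", "mu", "N")


class SweepError(RuntimeError):
    """A grid point failed; carries the offending parameter value."""

    def __init__(self, param: str, value, cause: Exception):
        super().__init__(f"sweep failed at {param}={value!r}: {cause}")
        self.param = param
        self.value = value
        self.cause = cause


def tracked_states(N: int) -> tuple[tuple[int, int, int], ...]:
    """The three canonical three-type equilibria tracked across sweeps:
    corner ``(N,0,0)``, edge midpoint ``(N/2,N/2,0)``, and center
    ``(N/3,N/3,N/3)``. Requires ``N`` divisible by 6."""
    if N % 6 != 0:
        raise ValueError("tracked_states requires N divisible by 6")
    return ((N, 0, 0), (N // 2, N // 2, 0), (N // 3, N // 3, N // 3))


def _default_tracked(n_types: int, N: int):
    if n_types == 3 and N % 6 == 0:
        return tracked_states(N)
    if n_types == 2 and N % 2 == 0:
        return ((N // 2, N // 2), (N, 0), (0, N))
    raise ValueError(
        "no default tracked states for this (n, N); pass tracked=... explicitly"
    )


def run_sweep(
    payoff,
    *,
    param: str,
    grid: Sequence,
    N: int | None = None,
    beta: float = 1.0,
    mu: float | None = None,
    kernel: str = "fermi",
    tracked: Sequence[tuple] | None = None,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> pd.DataFrame:
    """Sweep one of ``beta``, ``mu``, ``N`` over ``grid``, holding the other
    parameters fixed, and tabulate entropy rate, stationary probability,
    RTE and normalized RTE at the tracked states.

    For an ``N``-sweep with three types the tracked equilibria are
    recomputed per grid value (they live on different lattices); ``mu``
    left as ``None`` follows the conventional ``1/N`` scaling. The chain is
    rebuilt from scratch at every grid point and the output row order is
    deterministic.
    """
    payoff = np.asarray(payoff, dtype=float)
    n_types = payoff.shape[0]
    if param not in SWEEPABLE:
        raise ValueError(f"param must be one of {SWEEPABLE}")
    if param != "N" and N is None:
        raise ValueError("fixed population size N required")
    rows = []
    for value in grid:
        kw = {"beta": beta, "mu": mu, "kernel": kernel}
        this_N = N
        if param == "beta":
            kw["beta"] = float(value)
        elif param == "mu":
            kw["mu"] = float(value)
        else:
            this_N = int(value)
        if kw["mu"] is not None and not kw["mu"] > 0:
            raise ValueError("sweeps require mu > 0 (irreducible chains)")
        states = (
            tracked
            if tracked is not None and param != "N"
            else _default_tracked(n_types, this_N)
        )
        try:
            res = MoranModel(payoff, this_N, **kw).fit(tol=tol, max_iter=max_iter)
        except Exception as exc:  # noqa: BLE001 - re-raise with grid context
            raise SweepError(param, value, exc) from exc
        c = n_simplex_states(this_N, n_types)
        for v in states:
            s_v = res.stationary[v]
            rows.append(
                {
                    "param": param,
                    "value": value,
                    "N": this_N,
                    "n_states": c,
                    "entropy_rate": res.entropy_rate,
                    "state": format_state(v),
                    "stationary_probability": s_v,
                    "rte": res.rte[v],
                    "rte_normalized": res.rte[v] / c,
                }
            )
    return pd.DataFrame(rows)


def symmetry_check(
    payoff,
    *,
    N: int,
    beta: float,
    mu: float,
    permutation: Sequence[int],
    kernel: str = "fermi",
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> float:
    """Maximum absolute discrepancy ``max_a |s(a) - s(sigma(a))|`` of the
    stationary distribution under a permutation of the type indices.

    A payoff matrix invariant under ``sigma`` (with uniform mutation) makes
    the chain exactly equivariant, so the discrepancy is at solver-noise
    level; RTE is then constant along each permutation orbit."""
    perm = tuple(int(i) for i in permutation)
    n_types = np.asarray(payoff).shape[0]
    if sorted(perm) != list(range(n_types)):
        raise ValueError(f"permutation must be a bijection on 0..{n_types - 1}")
    res = MoranModel(payoff, N, mu=mu, beta=beta, kernel=kernel).fit(
        tol=tol, max_iter=max_iter
    )
    s = res.stationary
    worst = 0.0
    for a in s.states:
        sigma_a = tuple(a[perm.index(i)] for i in range(n_types))
        worst = max(worst, abs(s[a] - s[sigma_a]))
    return worst
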