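"""High-level model/results interface for the Moran process with mutation.

Mirrors the modelling-object idiom of statistical packages: a
:class:`MoranModel` is configured from the evolutionary parameters (payoff
matrix, population size N, mutation rate mu, selection intensity beta,
selection kernel); ``fit()`` builds the chain, solves the stationary
distribution, computes the entropy rate and per-state random trajectory
entropies, classifies the stationary extrema, and returns a
:class:`MoranResults` with a ``summary()`` table.
"""

from __future__ import annotations

from functools import cached_property
from typing import Hashable

import numpy as np
import pandas as pd

from . import markov, moran, stability, stationary as stat

__all__ = ["MoranModel", "MoranResults"]


class MoranModel:
    """The Moran process with mutation as a fittable model.

    Parameters
    ----------
    payoff
        Square ``n x n`` game matrix ``G`` (fitness ``f = G abar``).
    N
        Population size.
    mu
        Mutation rate of the uniform mutation matrix; defaults to ``1/N``,
        the conventional scaling.
    beta
        Selection intensity for the Fermi kernel (ignored by the linear
        kernel).
    kernel
        ``"fermi"`` (default) or ``"linear"``.
    """

    def __init__(
        self,
        payoff,
        N: int,
        *,
        mu: float | None = None,
        beta: float = 1.0,
        kernel: str = "fermi",
    ) -> None:
        self.payoff = np.asarray(payoff, dtype=float)
        self.N = int(N)
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        self.mu = 1.0 / self.N if mu is None else float(mu)
        self.beta = float(beta)
        self.kernel = kernel
        self.landscape = moran.GameLandscape(self.payoff, beta=self.beta, kernel=kernel)
        self.mutation = moran.uniform_mutation_matrix(self.landscape.n_types, self.mu)

    @classmethod
    def from_preset(cls, name: str, N: int, **kwargs) -> "MoranModel":
        """Build from a named payoff preset: ``hawkdove``, ``threetype``,
        ``rps``, or ``classical:<r>``."""
        return cls(moran.resolve_payoff(name), N, **kwargs)

    @classmethod
    def from_matrix_file(cls, path, N: int, **kwargs) -> "MoranModel":
        return cls(moran.load_payoff_matrix(path), N, **kwargs)

    @property
    def n_types(self) -> int:
        return self.landscape.n_types

    @property
    def n_states(self) -> int:
        return moran.n_simplex_states(self.N, self.n_types)

    @cached_property
    def chain(self) -> markov.FiniteMarkovProcess:
        """The assembled transition chain (built once, cached)."""
        return moran.build_moran_chain(self.N, self.landscape, self.mutation)

    def fit(
        self,
        *,
        method: str = "power",
        tol: float = 1e-12,
        max_iter: int = 10**6,
    ) -> "MoranResults":
        """Solve the stationary distribution (power iteration by default,
        ``method="exact"`` for two-type birth–death chains) and derive the
        entropy rate, RTEs, and extremum classification."""
        if method == "power":
            s = stat.stationary_power_iteration(self.chain, tol=tol, max_iter=max_iter)
        else:
            s = stat.solve_stationary(self.chain, method=method)
        h = markov.entropy_rate(self.chain, s)
        report = stability.rte_ranking(h, s)
        return MoranResults(self, s, h, report)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MoranModel(n={self.n_types}, N={self.N}, mu={self.mu:g}, "
            f"beta={self.beta:g}, kernel={self.kernel!r})"
        )


class MoranResults:
    """Fitted stability analysis of a :class:`MoranModel`."""

    def __init__(
        self,
        model: MoranModel,
        stationary_result: stat.StationaryResult,
        entropy_rate: float,
        report: stability.StabilityReport,
    ) -> None:
        self.model = model
        self.stationary = stationary_result
        self.entropy_rate = entropy_rate
        self.report = report

    # -- derived quantities ---------------------------------------------------

    @property
    def rte(self) -> dict[Hashable, float]:
        """Random trajectory entropy ``H_v = H(X)/s(v)`` per state (nats)."""
        return self.report.rte_by_state

    @property
    def normalized_rte(self) -> dict[Hashable, float]:
        """RTE divided by the state count ``C(N+n-1, n-1)``, for comparing
        processes with different population sizes."""
        c = self.model.n_states
        return {v: h / c for v, h in self.report.rte_by_state.items()}

    def most_stable(self, k: int = 1) -> tuple:
        """The ``k`` states with the smallest RTE (most stable first)."""
        return self.report.ranking[:k]

    def to_frame(self) -> pd.DataFrame:
        """Long-format results table, one row per state."""
        rows = []
        nrte = self.normalized_rte
        for v in self.stationary.states:
            row = {f"a{i + 1}": c for i, c in enumerate(v)}
            row.update(
                state=markov.format_state(v),
                stationary_probability=self.stationary[v],
                rte=self.report.rte_by_state[v],
                rte_normalized=nrte[v],
                classification=self.report.classification(v),
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the fitted stability analysis."""
        m = self.model
        rep = self.report
        fmt = markov.format_state
        lines = [
            "Moran process stability analysis (random trajectory entropy)",
            "=" * 62,
            f"types n:              {m.n_types}",
            f"population size N:    {m.N}   (states: {m.n_states})",
            f"mutation rate mu:     {m.mu:g}",
            f"selection beta:       {m.beta:g}   kernel: {m.kernel}",
            f"solver:               {self.stationary.method} "
            f"(residual {self.stationary.residual:.3e}, "
            f"iterations {self.stationary.iterations})",
            "-" * 62,
            f"entropy rate H(X):    {self.entropy_rate:.6f} nats/step",
            f"global stationary max: {fmt(rep.global_maximum) if rep.global_maximum is not None else 'tied'}"
            + (
                f"  (s = {self.stationary[rep.global_maximum]:.6g}, "
                f"RTE = {rep.rte_by_state[rep.global_maximum]:.6g})"
                if rep.global_maximum is not None
                else ""
            ),
            f"local maxima:         {sorted(map(fmt, rep.local_maxima))}",
            f"local minima:         {sorted(map(fmt, rep.local_minima))}",
            f"ties:                 {len(rep.ties)} state(s)",
            "-" * 62,
            "most stable states (ascending RTE):",
        ]
        for v in self.most_stable(min(5, len(self.stationary))):
            lines.append(
                f"  {fmt(v):>16}  s = {self.stationary[v]:.6g}  "
                f"RTE = {rep.rte_by_state[v]:.6g}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MoranResults(H={self.entropy_rate:.6g}, n_states={len(self.stationary)})"
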