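"""Extremum classification and RTE-based stability ranking.

A state of the simplex lattice is a *local maximum* of the stationary
distribution when its probability strictly exceeds that of every one-birth-
one-death neighbor; since the RTE of a state is ``H(X)/s(v)``, local maxima
of ``s`` are exactly local minima of the RTE (and vice versa) whenever the
entropy rate is positive — the duality this module makes checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np

from .markov import format_state, rte
from .stationary import StationaryResult

__all__ = [
    "StabilityReport",
    "neighbors",
    "classify_extrema",
    "rte_ranking",
]


def neighbors(state: Sequence[int]) -> frozenset[tuple[int, ...]]:
    """One-birth-one-death neighbors of a population state: all
    ``a + i_{u,w}`` with ``u != w`` and nonnegative entries. Interior states
    of an ``n``-type simplex have ``n(n-1)`` neighbors; boundary states
    fewer."""
    a = tuple(int(x) for x in state)
    n = len(a)
    out = set()
    for w in range(n):
        if a[w] == 0:
            continue
        for u in range(n):
            if u == w:
                continue
            b = list(a)
            b[u] += 1
            b[w] -= 1
            out.add(tuple(b))
    return frozenset(out)


@dataclass
class StabilityReport:
    """Per-state stability summary.

    ``local_maxima``/``local_minima`` use the strict definition; states
    that fail it only through equality with a neighbor land in ``ties``
    and are never classified as extrema. ``rte_by_state`` and ``ranking``
    (ascending RTE — most stable first) are filled by :func:`rte_ranking`;
    ``degenerate`` flags the zero-entropy-rate case where every RTE is 0
    and the ranking is meaningless.
    """

    local_maxima: frozenset = frozenset()
    local_minima: frozenset = frozenset()
    global_maximum: Hashable | None = None
    global_minimum: Hashable | None = None
    ties: frozenset = frozenset()
    rte_by_state: dict | None = None
    ranking: tuple | None = None
    degenerate: bool = False
    entropy_rate: float | None = None
    stationary: StationaryResult | None = None

    def to_csv(self, path: str | Path | None = None) -> str:
        """``state,stationary_probability,rte,classification`` rows."""
        if self.stationary is None:
            raise ValueError("report carries no stationary distribution")
        lines = ["state,stationary_probability,rte,classification"]
        for s in self.stationary.states:
            lines.append(
                f"{format_state(s)},{self.stationary[s]!r},"
                f"{'' if self.rte_by_state is None else repr(self.rte_by_state[s])},"
                f"{self.classification(s)}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def classification(self, state: Hashable) -> str:
        tags = []
        if state in self.local_maxima:
            tags.append("local_max")
        if state in self.local_minima:
            tags.append("local_min")
        if state == self.global_maximum:
            tags.append("global_max")
        if state == self.global_minimum:
            tags.append("global_min")
        if state in self.ties:
            tags.append("tie")
        return "+".join(tags) if tags else "none"

    def summary_json(self) -> str:
        def fmt_set(states):
            return sorted(format_state(s) for s in states)

        payload = {
            "local_maxima": fmt_set(self.local_maxima),
            "local_minima": fmt_set(self.local_minima),
            "global_maximum": None
            if self.global_maximum is None
            else format_state(self.global_maximum),
            "global_minimum": None
            if self.global_minimum is None
            else format_state(self.global_minimum),
            "ties": fmt_set(self.ties),
            "entropy_rate": self.entropy_rate,
            "degenerate": self.degenerate,
        }
        if self.stationary is not None:
            payload["solver"] = {
                "method": self.stationary.method,
                "residual": self.stationary.residual,
                "iterations": self.stationary.iterations,
            }
        return json.dumps(payload, indent=2)


def _neighbor_fn_for(states: Sequence[Hashable]) -> Callable[[Hashable], frozenset]:
    state_set = set(states)
    if all(isinstance(s, tuple) for s in states):
        return lambda v: frozenset(u for u in neighbors(v) if u in state_set)
    # Non-lattice chains (e.g. seeded fixtures): every other state is a
    # neighbor, so local and global extrema coincide.
    return lambda v: frozenset(state_set - {v})


def classify_extrema(
    values: Mapping[Hashable, float] | StationaryResult,
    *,
    eps: float = 0.0,
    neighbor_fn: Callable[[Hashable], frozenset] | None = None,
) -> StabilityReport:
    """Classify strict local and global extrema of a per-state value map
    (typically stationary probabilities) over the simplex lattice.

    ``v`` is a local maximum iff ``values[v] > values[u] + eps`` for every
    neighbor ``u`` (strictly; ``eps`` defaults to exact float comparison).
    States blocked from classification only by equality within ``eps`` are
    recorded in ``ties``. Global extrema must be unique, otherwise the
    tied states are reported in ``ties`` and the global slot stays empty.
    """
    if isinstance(values, StationaryResult):
        mapping: Mapping[Hashable, float] = values.as_dict()
        stat = values
    else:
        mapping = values
        stat = None
    states = list(mapping)
    if not states:
        raise ValueError("no states to classify")
    nb = neighbor_fn or _neighbor_fn_for(states)

    loc_max, loc_min, ties = set(), set(), set()
    for v in states:
        sv = mapping[v]
        nvals = [mapping[u] for u in nb(v)]
        if not nvals:
            continue
        if all(sv - u > eps for u in nvals):
            loc_max.add(v)
        elif all(u - sv > eps for u in nvals):
            loc_min.add(v)
        elif all(sv - u >= -eps for u in nvals) or all(u - sv >= -eps for u in nvals):
            ties.add(v)

    arr = np.array([mapping[v] for v in states])
    gmax_val, gmin_val = arr.max(), arr.min()
    gmax_states = [v for v in states if mapping[v] == gmax_val]
    gmin_states = [v for v in states if mapping[v] == gmin_val]
    gmax = gmax_states[0] if len(gmax_states) == 1 else None
    gmin = gmin_states[0] if len(gmin_states) == 1 else None
    if gmax is None:
        ties.update(gmax_states)
    if gmin is None:
        ties.update(gmin_states)

    return StabilityReport(
        local_maxima=frozenset(loc_max),
        local_minima=frozenset(loc_min),
        global_maximum=gmax,
        global_minimum=gmin,
        ties=frozenset(ties),
        stationary=stat,
    )


def rte_ranking(
    entropy_rate: float,
    stationary: StationaryResult,
    *,
    eps: float = 0.0,
) -> StabilityReport:
    """Random trajectory entropy per state via ``H_v = H(X)/s(v)`` and the
    resulting stability ranking (ascending RTE, most stable first).

    The ratio identity ``H_j / H_i = s(i) / s(j)`` holds by construction,
    so the extremum structure of the RTE mirrors that of the stationary
    distribution; the report's extrema fields describe the *stationary*
    distribution, with ``rte_by_state`` carrying the dual quantity. A zero
    entropy rate makes every RTE zero; the report is then flagged
    ``degenerate`` and the ranking left empty.
    """
    if entropy_rate < 0.0:
        raise ValueError("entropy rate must be nonnegative")
    probs = stationary.probabilities
    if (probs <= 0.0).any():
        bad = stationary.states[int(np.argmin(probs))]
        raise ValueError(f"zero stationary probability at state {bad!r}")
    rte_map = {v: rte(entropy_rate, stationary[v]) for v in stationary.states}
    report = classify_extrema(stationary, eps=eps)
    report.rte_by_state = rte_map
    report.entropy_rate = float(entropy_rate)
    if entropy_rate == 0.0:
        report.degenerate = True
        report.ranking = tuple()
    else:
        report.ranking = tuple(
            sorted(stationary.states, key=lambda v: (rte_map[v], str(v)))
        )
    return report
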