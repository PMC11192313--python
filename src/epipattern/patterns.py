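"""Infection patterns: who-infected-whom matrices and node indices.

The infection pattern of a contagion process is the directed non-negative
matrix **C** whose entry ``C_ij`` is the probability, averaged over
stochastic realizations, that node *i* directly infected node *j*.  It is
estimated by summing, over all runs, the attribution fraction of every
infection event of *j* that names *i*, and dividing by the number of runs.
Runs with no infection events still count in the denominator.

Row sums of **C** give the spreader index ``s_i`` (expected number of nodes
*i* infects per run) and column sums the receiver index ``r_i`` (probability
that *i* is infected as a non-seed), the out- and in-strengths of the
directed infection-pattern network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simple_models import InfectionEventLog, RunSummary

__all__ = [
    "InfectionPattern",
    "NodeIndices",
    "build_infection_pattern",
    "time_pattern_curve",
    "node_indices",
    "filter_runs_by_attack_rate",
    "attack_rate_mode",
    "write_pattern",
]

_FILTERS = {"all": None, "link_only": {"link"}, "triad_only": {"triad"}}


@dataclass
class InfectionPattern:
    """Sparse directed matrix C keyed by ordered (infector, infectee) indices."""

    entries: dict[tuple[int, int], float]
    index: dict[str, int]
    n_runs: int
    time_cutoff: float = math.inf
    mechanism_filter: str = "all"

    @property
    def n_nodes(self) -> int:
        return len(self.index)

    def to_dense(self) -> np.ndarray:
        c = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), v in self.entries.items():
            c[i, j] = v
        return c

    def total(self) -> float:
        """Sum of all entries = mean number of infection events per run."""
        return float(sum(self.entries.values()))


@dataclass(frozen=True)
class NodeIndices:
    """Spreader (out-strength) and receiver (in-strength) index per node."""

    spreader: dict[str, float]
    receiver: dict[str, float]


def build_infection_pattern(
    logs: Iterable[InfectionEventLog],
    index: Mapping[str, int],
    time_cutoff: float = math.inf,
    mechanism_filter: str = "all",
) -> InfectionPattern:
    """Average attribution fractions over runs into the pattern matrix.

    ``mechanism_filter`` restricts to pairwise (``link_only``) or group
    (``triad_only``) contagion events, giving the C1/C2 decomposition of a
    simplicial pattern (C1 + C2 = C).
    """
    if mechanism_filter not in _FILTERS:
        raise ValueError(f"unknown mechanism_filter {mechanism_filter!r}")
    allowed = _FILTERS[mechanism_filter]
    logs = list(logs)
    if not logs:
        raise ValueError("cannot build a pattern from zero runs")
    sums: dict[tuple[int, int], float] = {}
    for log in logs:
        for ev in log.events:
            if ev.time > time_cutoff:
                continue
            if allowed is not None and ev.mechanism not in allowed:
                continue
            j = index[ev.infectee]
            for infector, frac in ev.attribution.items():
                key = (index[infector], j)
                sums[key] = sums.get(key, 0.0) + frac
    n_runs = len(logs)
    entries = {k: v / n_runs for k, v in sums.items()}
    return InfectionPattern(
        entries=entries,
        index=dict(index),
        n_runs=n_runs,
        time_cutoff=time_cutoff,
        mechanism_filter=mechanism_filter,
    )


def time_pattern_curve(
    logs: Iterable[InfectionEventLog],
    index: Mapping[str, int],
    time_grid: Sequence[float],
) -> list[InfectionPattern]:
    """Time-resolved patterns C(t): events up to each grid time.

    Entries are non-decreasing along the (ascending) grid.
    """
    grid = list(time_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("time_grid must be sorted ascending")
    logs = list(logs)
    return [build_infection_pattern(logs, index, time_cutoff=t) for t in grid]


def node_indices(p: InfectionPattern) -> NodeIndices:
    """Row sums (spreader) and column sums (receiver) of the pattern."""
    rev = {v: k for k, v in p.index.items()}
    s = {node: 0.0 for node in p.index}
    r = {node: 0.0 for node in p.index}
    for (i, j), v in p.entries.items():
        s[rev[i]] += v
        r[rev[j]] += v
    return NodeIndices(spreader=s, receiver=r)


def filter_runs_by_attack_rate(
    logs: Sequence[InfectionEventLog],
    summaries: Sequence[RunSummary],
    lo: float,
    hi: float,
) -> tuple[list[InfectionEventLog], int]:
    """Runs whose final attack rate lies in the closed window [lo, hi]."""
    if not 0 <= lo < hi <= 1:
        raise ValueError("need 0 <= lo < hi <= 1")
    by_id = {s.run_id: s.final_attack_rate for s in summaries}
    kept = [log for log in logs if lo <= by_id[log.run_id] <= hi]
    return kept, len(kept)


def attack_rate_mode(
    summaries: Sequence[RunSummary] | Sequence[float],
    bin_width: float = 0.02,
    zero_cutoff: float = 0.1,
) -> float | None:
    """Center of the dominant attack-rate histogram bin above ``zero_cutoff``.

    Attack-rate distributions of SIR-like processes are typically bimodal
    (early die-out near zero vs. full epidemic); this returns the location of
    the epidemic (non-zero) mode, or None when no run exceeds ``zero_cutoff``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(summaries) == 0:
        raise ValueError("need at least one run summary")
    rates = np.array(
        [s.final_attack_rate if isinstance(s, RunSummary) else float(s) for s in summaries]
    )
    if not (rates > zero_cutoff).any():
        return None
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.arange(0, (n_bins + 1)) * bin_width
    counts, _ = np.histogram(rates, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    eligible = centers > zero_cutoff
    counts = np.where(eligible, counts, -1)
    best = int(np.argmax(counts))
    return float(centers[best])


def write_pattern(p: InfectionPattern, path: str | Path, dense: bool = False) -> None:
    """TSV export: sparse (i, j, C_ij) or the dense matrix with a node header."""
    rev = {v: k for k, v in p.index.items()}
    with open(path, "w") as fh:
        if dense:
            order = sorted(p.index, key=p.index.get)  # type: ignore[arg-type]
            fh.write("\t".join(order) + "\n")
            for row in p.to_dense():
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
        else:
            fh.write("i\tj\tC_ij\n")
            for (i, j), v in sorted(p.entries.items()):
                fh.write(f"{rev[i]}\t{rev[j]}\t{v:.10g}\n")
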