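"""Synthetic contact-event generator and analytic toy graphs.

``generate_school_like_events`` emulates the statistical structure of a
primary-school contact dataset: a population partitioned into classes
(communities) with dense within-class and sparse between-class mixing,
heavy-tailed per-pair contact counts, and frequent simultaneous triangles
("gatherings") that create size-3 hyperedges in the aggregated hypergraph.
A ``weight_correlation`` knob controls how strongly gatherings recur on a
persistent subset of triples: recurring triples accumulate both triad counts
and pairwise counts, reproducing the empirically observed positive coupling
between link weights and triad weights (and, at 0, its absence — the
decorrelated regime needed by weight-shuffling experiments).

The defaults (10 classes of 24, 2000 snapshots) are sized like one day of a
primary-school deployment, so experiment recipes written against real data
transfer unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .substrate import ContactEventList, WeightedContactGraph

__all__ = [
    "SchoolLikeSpec",
    "generate_school_like_events",
    "write_contact_events",
    "make_toy_graph",
]


@dataclass(frozen=True)
class SchoolLikeSpec:
    """Parameters of the school-like contact generator.

    p_within / p_between are per-snapshot activation probabilities of a
    within-class / between-class pair (before the heavy-tail modulation);
    p_gather is the per-class per-snapshot probability of a triangle
    gathering; weight_correlation in [0, 1] sets the fraction of gatherings
    drawn from a small persistent pool of triples.
    """

    n_groups: int = 10
    group_size: int = 24
    n_snapshots: int = 2000
    p_within: float = 0.01
    p_between: float = 0.0005
    p_gather: float = 0.02
    weight_correlation: float = 0.5
    rng_seed: int = 0
    resolution: int = 20

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between", "p_gather", "weight_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_groups * self.group_size < 3:
            raise ValueError("need at least 3 nodes")
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")


def _node_ids(spec: SchoolLikeSpec) -> list[list[str]]:
    width = len(str(spec.n_groups * spec.group_size - 1))
    groups = []
    k = 0
    for _ in range(spec.n_groups):
        groups.append([f"n{str(k + m).zfill(width)}" for m in range(spec.group_size)])
        k += spec.group_size
    return groups


def generate_school_like_events(spec: SchoolLikeSpec) -> ContactEventList:
    """Draw a contact-event list with community structure and gatherings.

    Per-pair activation probabilities are ``p * X`` with X Pareto-distributed
    (mean 1, tail index 2), capped at 1, giving heavy-tailed contact counts.
    A gathering emits all three pair records of the chosen triple at the same
    timestamp, so the snapshot graph contains the triangle.
    """
    rng = np.random.default_rng(spec.rng_seed)
    groups = _node_ids(spec)
    n_snap = spec.n_snapshots
    records: list[tuple[int, str, str]] = []

    def _activate(pairs: list[tuple[str, str]], p: float, heavy: bool) -> None:
        if p <= 0 or not pairs:
            return
        if heavy:
            # Pareto(alpha=2) has mean alpha/(alpha-1) = 2; halve for mean 1.
            mult = (1.0 + rng.pareto(2.0, size=len(pairs))) / 2.0
            probs = np.minimum(p * mult, 1.0)
        else:
            probs = np.full(len(pairs), p)
        counts = rng.binomial(n_snap, probs)
        for (i, j), c in zip(pairs, counts):
            if c:
                for s in rng.choice(n_snap, size=c, replace=False):
                    records.append((int(s) * spec.resolution, i, j))

    for g in groups:
        _activate(list(itertools.combinations(g, 2)), spec.p_within, heavy=True)
    between = [
        (i, j)
        for ga, gb in itertools.combinations(groups, 2)
        for i in ga
        for j in gb
    ]
    _activate(between, spec.p_between, heavy=False)

    # Gatherings: per class and snapshot, w.p. p_gather emit a triangle.
    if spec.p_gather > 0:
        for g in groups:
            if len(g) < 3:
                continue
            # persistent pool: a few favored triples that gather repeatedly
            pool = [
                tuple(sorted(rng.choice(g, size=3, replace=False))) for _ in range(3)
            ]
            snaps = np.flatnonzero(rng.random(n_snap) < spec.p_gather)
            for s in snaps:
                if rng.random() < spec.weight_correlation:
                    tri = pool[rng.integers(len(pool))]
                else:
                    tri = tuple(sorted(rng.choice(g, size=3, replace=False)))
                t = int(s) * spec.resolution
                a, b, c = tri
                records.extend([(t, a, b), (t, a, c), (t, b, c)])

    if not records:
        raise ValueError("no contacts generated: degenerate spec")
    return ContactEventList.from_records(records, resolution=spec.resolution)


def write_contact_events(events: ContactEventList, path) -> None:
    """Emit the SocioPatterns dialect read back by ``read_contact_events``."""
    with open(path, "w") as fh:
        for t, i, j in events.records:
            fh.write(f"{t}\t{i}\t{j}\n")


def make_toy_graph(
    kind: str, size: int, weights: list[float] | None = None
) -> WeightedContactGraph:
    """Small deterministic fixture graphs with known infection behaviour.

    kinds: ``two_node`` (single edge), ``star`` (center ``c`` plus
    ``size - 1`` leaves), ``chain`` (path of ``size`` nodes), ``fig2_like``
    (a small heterogeneously weighted community pair whose infection pattern
    is visibly asymmetric).  Weights default to all 1 and are renormalized so
    the maximum is exactly 1.
    """
    if kind == "two_node":
        if size != 2:
            raise ValueError("two_node requires size=2")
        w = weights or [1.0]
        return WeightedContactGraph.from_weights({("a", "b"): w[0]})
    if kind == "star":
        if size < 2:
            raise ValueError("star requires size>=2")
        n_leaves = size - 1
        w = weights or [1.0] * n_leaves
        if len(w) != n_leaves:
            raise ValueError(f"star of size {size} needs {n_leaves} weights")
        return WeightedContactGraph.from_weights(
            {("c", f"l{k}"): w[k] for k in range(n_leaves)}
        )
    if kind == "chain":
        if size < 2:
            raise ValueError("chain requires size>=2")
        w = weights or [1.0] * (size - 1)
        if len(w) != size - 1:
            raise ValueError(f"chain of size {size} needs {size - 1} weights")
        names = [chr(ord("a") + k) for k in range(size)]
        return WeightedContactGraph.from_weights(
            {(names[k], names[k + 1]): w[k] for k in range(size - 1)}
        )
    if kind == "fig2_like":
        # two loosely bridged triangles with heterogeneous weights
        edges = {
            ("a", "b"): 1.0,
            ("a", "c"): 0.6,
            ("b", "c"): 0.8,
            ("c", "d"): 0.2,
            ("d", "e"): 0.9,
            ("d", "f"): 0.5,
            ("e", "f"): 0.7,
        }
        return WeightedContactGraph.from_weights(edges)
    raise ValueError(f"unknown toy graph kind {kind!r}")
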