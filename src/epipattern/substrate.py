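"""Weighted contact graphs and hypergraphs from time-resolved proximity data.

Face-to-face contact datasets (e.g. the public SocioPatterns recordings) come
as lists of ``t i j`` records: individuals *i* and *j* were in contact during
the 20-second slice starting at *t*.  Temporal aggregation turns these into a
weighted static graph, where the weight of link *ij* is the number of slices
the pair co-occurred in, normalized by the maximum over all pairs:
``W_ij = n_ij / n_max``.  Group (higher-order) interactions are extracted from
the per-timestamp *snapshot graphs*: every clique of simultaneously
interacting nodes of size >= 3 is decomposed into its triads, and the weight
of hyperedge *ijk* is the number of snapshots containing the triad,
normalized by the maximum triad count.
"""

from __future__ import annotations

import gzip
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEventList",
    "WeightedContactGraph",
    "WeightedHypergraph",
    "read_contact_events",
    "aggregate_weighted_graph",
    "build_weighted_hypergraph",
    "shuffle_triad_weights",
    "shuffle_edge_weights",
    "write_edge_list",
    "write_triad_list",
]


class ContactParseError(ValueError):
    """A contact-list line could not be parsed."""


def _pair(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


def _triple(i: str, j: str, k: str) -> tuple[str, str, str]:
    return tuple(sorted((i, j, k)))  # type: ignore[return-value]


@dataclass(frozen=True)
class ContactEventList:
    """Deduplicated, time-sorted list of pairwise contact records.

    Each record is ``(t, i, j)``: node ids *i* != *j* were in contact during
    the slice starting at integer time *t*.  ``resolution`` is the slice
    length in seconds (20 s for SocioPatterns data).
    """

    records: tuple[tuple[int, str, str], ...]
    resolution: int = 20

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, str, str]], resolution: int = 20
    ) -> "ContactEventList":
        """Build from raw records: drops exact duplicates, sorts by time."""
        seen = {(t, *_pair(str(i), str(j))) for t, i, j in records}
        ordered = tuple(sorted(seen))
        return cls(records=ordered, resolution=resolution)

    def __len__(self) -> int:
        return len(self.records)

    def nodes(self) -> list[str]:
        ids = {i for _, i, _ in self.records} | {j for _, _, j in self.records}
        return sorted(ids)

    def timestamps(self) -> list[int]:
        return sorted({t for t, _, _ in self.records})


@dataclass
class WeightedContactGraph:
    """Static weighted contact graph: ``W_ij = n_ij / n_max``.

    ``nodes`` is sorted; ``index`` maps node id to a stable integer used by
    every matrix in the pipeline.  ``edges`` maps the sorted id pair to
    ``(n_ij, W_ij)``.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], tuple[float, float]]
    n_max: float
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {v: k for k, v in enumerate(self.nodes)}
        self._adj: list[tuple[np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_weights(
        cls, weights: Mapping[tuple[str, str], float], nodes: Sequence[str] | None = None
    ) -> "WeightedContactGraph":
        """Build a fixture graph from raw pair weights (renormalized to max 1)."""
        if not weights:
            raise ValueError("cannot build a graph without edges")
        w_max = max(weights.values())
        if w_max <= 0:
            raise ValueError("all weights non-positive")
        edges = {_pair(*e): (float(w), float(w) / w_max) for e, w in weights.items()}
        ids = set(nodes or [])
        for a, b in edges:
            ids.update((a, b))
        return cls(nodes=sorted(ids), edges=edges, n_max=float(w_max))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, i: str, j: str) -> float:
        return self.edges.get(_pair(i, j), (0.0, 0.0))[1]

    def adjacency(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per node-index: (neighbor index array, normalized weight array)."""
        if self._adj is None:
            nbrs: list[list[tuple[int, float]]] = [[] for _ in self.nodes]
            for (a, b), (_, w) in self.edges.items():
                ia, ib = self.index[a], self.index[b]
                nbrs[ia].append((ib, w))
                nbrs[ib].append((ia, w))
            self._adj = [
                (
                    np.array([n for n, _ in lst], dtype=np.int64),
                    np.array([w for _, w in lst], dtype=np.float64),
                )
                for lst in nbrs
            ]
        return self._adj

    def total_weights(self) -> np.ndarray:
        """Sum of normalized link weights per node index (weighted degree)."""
        tw = np.zeros(self.n_nodes)
        for (a, b), (_, w) in self.edges.items():
            tw[self.index[a]] += w
            tw[self.index[b]] += w
        return tw


@dataclass
class WeightedHypergraph:
    """A weighted contact graph plus weighted size-3 hyperedges (triads)."""

    base: WeightedContactGraph
    triads: dict[tuple[str, str, str], tuple[float, float]]
    n2_max: float

    @property
    def nodes(self) -> list[str]:
        return self.base.nodes

    @property
    def index(self) -> dict[str, int]:
        return self.base.index

    def triad_weight(self, i: str, j: str, k: str) -> float:
        return self.triads.get(_triple(i, j, k), (0.0, 0.0))[1]


def read_contact_events(path: str | Path, resolution: int = 20) -> ContactEventList:
    """Parse a SocioPatterns-dialect contact list (``t i j`` per line).

    Extra columns (class / role metadata) are ignored; ``.gz`` files are
    transparently decompressed.  Self-loop records (``i == j``) are dropped
    with a logged warning; a malformed line raises :class:`ContactParseError`
    naming the line number.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[tuple[int, str, str]] = []
    n_self = 0
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ContactParseError(
                    f"{path}:{lineno}: expected at least 3 fields, got {len(parts)}"
                )
            try:
                t = int(parts[0])
            except ValueError as exc:
                raise ContactParseError(
                    f"{path}:{lineno}: first field {parts[0]!r} is not an integer time"
                ) from exc
            i, j = parts[1], parts[2]
            if i == j:
                n_self += 1
                continue
            records.append((t, i, j))
    if n_self:
        logger.warning("%s: dropped %d self-loop record(s)", path, n_self)
    return ContactEventList.from_records(records, resolution=resolution)


def aggregate_weighted_graph(events: ContactEventList) -> WeightedContactGraph:
    """Temporal aggregation: count co-occurrences per pair, normalize by max."""
    if len(events) == 0:
        raise ValueError("cannot aggregate an empty event list (n_max undefined)")
    counts: dict[tuple[str, str], int] = {}
    for _, i, j in events.records:
        key = _pair(i, j)
        counts[key] = counts.get(key, 0) + 1
    n_max = max(counts.values())
    edges = {e: (float(n), n / n_max) for e, n in counts.items()}
    return WeightedContactGraph(nodes=events.nodes(), edges=edges, n_max=float(n_max))


def build_weighted_hypergraph(events: ContactEventList) -> WeightedHypergraph:
    """Extract weighted triads from per-timestamp snapshot graphs.

    In each snapshot graph every maximal clique of size >= 3 is decomposed
    into all its triads; a triad is counted at most once per snapshot,
    however many cliques contain it.  ``W^D_ijk = n_ijk / n2_max``.
    """
    base = aggregate_weighted_graph(events)
    counts: dict[tuple[str, str, str], int] = {}
    by_time: dict[int, list[tuple[str, str]]] = {}
    for t, i, j in events.records:
        by_time.setdefault(t, []).append((i, j))
    for t, pairs in by_time.items():
        snap = nx.Graph(pairs)
        triads_here: set[tuple[str, str, str]] = set()
        for clique in nx.find_cliques(snap):
            if len(clique) >= 3:
                triads_here.update(
                    _triple(*c) for c in itertools.combinations(clique, 3)
                )
        for tri in triads_here:
            counts[tri] = counts.get(tri, 0) + 1
    if counts:
        n2_max = max(counts.values())
        triads = {tri: (float(n), n / n2_max) for tri, n in counts.items()}
    else:
        n2_max, triads = 0, {}
    return WeightedHypergraph(base=base, triads=triads, n2_max=float(n2_max))


def shuffle_triad_weights(hg: WeightedHypergraph, rng_seed: int) -> WeightedHypergraph:
    """Random permutation of triad weights across the existing triads.

    Destroys the empirical correlation between a triad's weight and the
    weights of its three constituent links while leaving the link weights
    and triad membership untouched.
    """
    if len(hg.triads) < 2:
        raise ValueError("need at least 2 triads to shuffle")
    rng = np.random.default_rng(rng_seed)
    keys = sorted(hg.triads)
    values = [hg.triads[k] for k in keys]
    perm = rng.permutation(len(keys))
    shuffled = {k: values[p] for k, p in zip(keys, perm)}
    return WeightedHypergraph(base=hg.base, triads=shuffled, n2_max=hg.n2_max)


def shuffle_edge_weights(
    graph: WeightedContactGraph, rng_seed: int
) -> WeightedContactGraph:
    """Topology-preserving null model: permute link weights across edges."""
    if len(graph.edges) < 2:
        raise ValueError("need at least 2 edges to shuffle")
    rng = np.random.default_rng(rng_seed)
    keys = sorted(graph.edges)
    values = [graph.edges[k] for k in keys]
    perm = rng.permutation(len(keys))
    shuffled = {k: values[p] for k, p in zip(keys, perm)}
    return WeightedContactGraph(nodes=list(graph.nodes), edges=shuffled, n_max=graph.n_max)


def write_edge_list(graph: WeightedContactGraph, path: str | Path) -> None:
    """TSV export: i, j, n_ij, W_ij."""
    with open(path, "w") as fh:
        fh.write("i\tj\tn_ij\tW_ij\n")
        for (a, b), (n, w) in sorted(graph.edges.items()):
            fh.write(f"{a}\t{b}\t{n:g}\t{w:.10g}\n")


def write_triad_list(hg: WeightedHypergraph, path: str | Path) -> None:
    """TSV export: i, j, k, n_ijk, W_ijk."""
    with open(path, "w") as fh:
        fh.write("i\tj\tk\tn_ijk\tW_ijk\n")
        for (a, b, c), (n, w) in sorted(hg.triads.items()):
            fh.write(f"{a}\t{b}\t{c}\t{n:g}\t{w:.10g}\n")
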