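"""Complex-contagion simulators: simplicial SIR and the weighted threshold model.

Simplicial contagion runs on a weighted hypergraph: a susceptible node *i*
feels a pairwise hazard ``beta_link * W_ij`` from each infectious neighbour
*j* and, additionally, a group hazard ``beta_tri * W^D_ikl`` from each triad
``(i, k, l)`` whose other two members are *both* currently infectious.  All
hazards and the recovery rate ``mu_I`` are constant, so the dynamics are
Markovian and simulated exactly with the Gillespie algorithm.  A triad-driven
infection is attributed half-and-half to the two infectious members — they
play an equivalent role in the group event, regardless of their individual
link weights to the target.

The threshold model is a deterministic-infection SIR on the weighted graph:
at each synchronous step of length ``dt`` a susceptible node becomes
infectious when the summed weight of its links to currently infectious
neighbours, divided by its total link weight (all neighbours, recovered
included), strictly exceeds ``theta``.  The infection is attributed to the
infectious neighbours proportionally to their link weights.  Infectious nodes
recover independently with per-step probability ``1 - exp(-mu_I * dt)``;
the recovery durations are pre-drawn per node from a node-indexed stream, so
a node draws the same infectious duration whatever step it is infected at
(which makes the ever-infected set shrink monotonically as theta grows, on a
fixed seed and randomness stream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simple_models import InfectionEvent, InfectionEventLog, RunSummary, child_seed
from .substrate import WeightedContactGraph, WeightedHypergraph

__all__ = [
    "SimplicialParams",
    "ThresholdParams",
    "simulate_simplicial",
    "simulate_threshold",
    "simulate_complex_runs",
]


@dataclass(frozen=True)
class SimplicialParams:
    """Pairwise rate scale beta_link, triadic rate scale beta_tri, recovery mu_I."""

    beta_link: float
    beta_tri: float
    mu_I: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_link < 0 or self.beta_tri < 0:
            raise ValueError("beta rates must be >= 0")
        if self.mu_I <= 0:
            raise ValueError("mu_I must be > 0")


@dataclass(frozen=True)
class ThresholdParams:
    """Weighted-fraction threshold theta in (0,1), recovery rate mu_I, step dt."""

    theta: float
    mu_I: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.mu_I <= 0:
            raise ValueError("mu_I must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def _resolve_seed_ids(
    nodes: list[str], index: dict[str, int], seed_node, rng: np.random.Generator
) -> list[int]:
    if isinstance(seed_node, str):
        if seed_node == "random":
            return [int(rng.integers(len(nodes)))]
        if seed_node not in index:
            raise ValueError(f"seed node {seed_node!r} not in substrate")
        return [index[seed_node]]
    idxs = [index[s] for s in seed_node]
    if not idxs:
        raise ValueError("empty seed collection")
    return idxs


def simulate_simplicial(
    hg: WeightedHypergraph,
    params: SimplicialParams,
    seed_node: str | Sequence[str] = "random",
    rng_seed: int | Sequence[int] = 0,
    run_id: int = 0,
) -> tuple[InfectionEventLog, RunSummary]:
    """Exact Gillespie realization of simplicial SIR on a weighted hypergraph.

    Link infections carry attribution ``{j: 1}`` with mechanism ``link``;
    triad infections carry ``{k: 0.5, l: 0.5}`` with mechanism ``triad``.
    """
    graph = hg.base
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty substrate")
    rng = np.random.default_rng(rng_seed)
    nodes = graph.nodes
    adj = graph.adjacency()

    # triads per node, as (other1, other2, triad weight) index triples
    tri_of: list[list[tuple[int, int, float]]] = [[] for _ in range(n)]
    for (a, b, c), (_, w) in hg.triads.items():
        ia, ib, ic = graph.index[a], graph.index[b], graph.index[c]
        tri_of[ia].append((ib, ic, w))
        tri_of[ib].append((ia, ic, w))
        tri_of[ic].append((ia, ib, w))

    S, I, R = 0, 1, 2
    state = np.zeros(n, dtype=np.int8)
    link_haz = np.zeros(n)
    tri_haz = np.zeros(n)
    bl, bt, mu = params.beta_link, params.beta_tri, params.mu_I

    def set_infectious(u: int) -> None:
        state[u] = I
        nbrs, wts = adj[u]
        for k, v in enumerate(nbrs):
            if state[v] == S:
                link_haz[v] += bl * wts[k]
        for a, b, w in tri_of[u]:
            # u just turned infectious: triad pressures its susceptible third
            # member iff exactly one of (a, b) is infectious and the other is S
            if state[a] == I and state[b] == S:
                tri_haz[b] += bt * w
            elif state[b] == I and state[a] == S:
                tri_haz[a] += bt * w

    def set_recovered(u: int) -> None:
        state[u] = R
        nbrs, wts = adj[u]
        for k, v in enumerate(nbrs):
            if state[v] == S:
                link_haz[v] -= bl * wts[k]
        for a, b, w in tri_of[u]:
            if state[a] == I and state[b] == S:
                tri_haz[b] -= bt * w
            elif state[b] == I and state[a] == S:
                tri_haz[a] -= bt * w

    log = InfectionEventLog(run_id=run_id, seed_node=seed_node)
    t = 0.0
    seeds = _resolve_seed_ids(nodes, graph.index, seed_node, rng)
    for s in seeds:
        set_infectious(s)
        log.stage_history[nodes[s]] = [("I", 0.0)]
    if isinstance(seed_node, str) and seed_node == "random":
        log.seed_node = nodes[seeds[0]]

    n_infectious = len(seeds)
    while n_infectious > 0:
        sus_mask = state == S
        haz_all = np.maximum(link_haz + tri_haz, 0.0)
        inf_rate = float(haz_all[sus_mask].sum())
        total = mu * n_infectious + inf_rate
        t += float(rng.exponential(1.0 / total))
        if rng.random() < mu * n_infectious / total:
            infectious_nodes = np.flatnonzero(state == I)
            u = int(infectious_nodes[rng.integers(len(infectious_nodes))])
            set_recovered(u)
            log.stage_history[nodes[u]].append(("R", t))
            n_infectious -= 1
            continue
        # infection: pick the susceptible target proportionally to its hazard
        haz = np.where(sus_mask, haz_all, 0.0)
        u = int(rng.choice(n, p=haz / haz.sum()))
        # then the channel: an infectious neighbour link, or an active triad
        channels: list[tuple[float, dict[str, float], str]] = []
        nbrs, wts = adj[u]
        for k, v in enumerate(nbrs):
            if state[v] == I and bl > 0:
                channels.append((bl * wts[k], {nodes[v]: 1.0}, "link"))
        for a, b, w in tri_of[u]:
            if state[a] == I and state[b] == I and bt > 0:
                channels.append(
                    (bt * w, {nodes[a]: 0.5, nodes[b]: 0.5}, "triad")
                )
        rates = np.array([c[0] for c in channels])
        pick = int(rng.choice(len(channels), p=rates / rates.sum()))
        _, attribution, mechanism = channels[pick]
        log.events.append(
            InfectionEvent(
                time=t, infectee=nodes[u], attribution=attribution, mechanism=mechanism
            )
        )
        set_infectious(u)
        log.stage_history[nodes[u]] = [("I", t)]
        n_infectious += 1

    n_inf = log.n_ever_infected()
    summary = RunSummary(
        run_id=run_id,
        seed_node=log.seed_node,
        final_attack_rate=n_inf / n,
        end_time=t,
    )
    return log, summary


def simulate_threshold(
    graph: WeightedContactGraph,
    params: ThresholdParams,
    seed_node: str | Sequence[str] = "random",
    rng_seed: int | Sequence[int] = 0,
    run_id: int = 0,
) -> tuple[InfectionEventLog, RunSummary]:
    """Synchronous weighted threshold SIR on a weighted graph.

    Infection decisions in a step use the state at the start of the step;
    newly infected nodes become infectious at the end of the step (event time
    ``step * dt``).  An isolated node (zero total weight) is never infected.
    """
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(rng_seed)
    nodes = graph.nodes
    adj = graph.adjacency()
    total_w = graph.total_weights()

    # Per-node infectious duration in steps, geometric with the per-step
    # recovery probability; drawn up front from the node-indexed stream so the
    # duration is the same whenever (and whether) the node gets infected.
    q = 1.0 - np.exp(-params.mu_I * params.dt)
    durations = rng.geometric(q, size=n)

    S, I, R = 0, 1, 2
    state = np.zeros(n, dtype=np.int8)
    remaining = np.zeros(n, dtype=np.int64)

    log = InfectionEventLog(run_id=run_id, seed_node=seed_node)
    seeds = _resolve_seed_ids(nodes, graph.index, seed_node, rng)
    for s in seeds:
        state[s] = I
        remaining[s] = durations[s]
        log.stage_history[nodes[s]] = [("I", 0.0)]
    if isinstance(seed_node, str) and seed_node == "random":
        log.seed_node = nodes[seeds[0]]

    t = 0.0
    while (state == I).any():
        t += params.dt
        infectious = state == I
        # infection sweep against start-of-step state
        newly: list[tuple[int, dict[str, float]]] = []
        for u in np.flatnonzero(state == S):
            if total_w[u] <= 0:
                continue
            nbrs, wts = adj[u]
            mask = infectious[nbrs]
            w_inf = float(wts[mask].sum())
            if w_inf / total_w[u] > params.theta:
                contrib = {
                    nodes[int(v)]: float(w) / w_inf
                    for v, w in zip(nbrs[mask], wts[mask])
                }
                newly.append((u, contrib))
        # recovery of nodes infectious during this step
        for u in np.flatnonzero(infectious):
            remaining[u] -= 1
            if remaining[u] <= 0:
                state[u] = R
                log.stage_history[nodes[u]].append(("R", t))
        for u, contrib in newly:
            state[u] = I
            remaining[u] = durations[u]
            log.stage_history[nodes[u]] = [("I", t)]
            log.events.append(
                InfectionEvent(
                    time=t, infectee=nodes[u], attribution=contrib, mechanism="threshold"
                )
            )

    summary = RunSummary(
        run_id=run_id,
        seed_node=log.seed_node,
        final_attack_rate=log.n_ever_infected() / n,
        end_time=t,
    )
    return log, summary


def simulate_complex_runs(
    substrate: WeightedHypergraph | WeightedContactGraph,
    params: SimplicialParams | ThresholdParams,
    n_runs: int,
    rng_seed: int,
    seed_node: str | Sequence[str] = "random",
) -> tuple[list[InfectionEventLog], list[RunSummary]]:
    """Independent realizations; run *k* uses the stream ``[rng_seed, k]``."""
    sim = simulate_simplicial if isinstance(params, SimplicialParams) else simulate_threshold
    logs, summaries = [], []
    for k in range(n_runs):
        log, summ = sim(  # type: ignore[operator]
            substrate, params, seed_node=seed_node, rng_seed=child_seed(rng_seed, k), run_id=k
        )
        logs.append(log)
        summaries.append(summ)
    return logs, summaries
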