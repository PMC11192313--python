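"""Event-driven stochastic simulators for simple contagion on weighted graphs.

All models are agent-based SIR-family compartmental processes on a static
weighted contact graph: an infectious node transmits along each link to a
susceptible neighbour as an independent exponential clock of rate
``r * beta * W_ij``, where *r* is the relative transmissibility of the
current infectious stage.  Stage durations are gamma distributed, drawn at
the moment a node enters the stage; with a dispersion ratio eta = 1 the gamma
reduces to the exponential, i.e. the Markovian model.

The scheme is exact (next-reaction): when a node becomes infected its stage
durations are drawn, then per-edge transmission delays; delays landing inside
an infectious window are pushed onto a global event queue and resolved in
time order, discarding candidates whose target is no longer susceptible.
The first successful transmission fixes the single infector of a node, so a
simple-contagion infection event always carries attribution ``{infector: 1}``.

Model variants (rates per unit time; the time unit is arbitrary — rescaling
all rates only changes the global time scale):

* ``SIR`` — susceptible / infectious / recovered, recovery rate mu_I.
* ``SEIRe1 / SEIRe4 / SEIRi4`` — Markovian SEIR; the suffix marks which
  stage's mean duration is stretched by a factor 4.
* ``*v025`` variants — same means, non-Markovian gamma durations with
  std/mean ratio eta = 0.25.
* ``COVID`` — exposed (non-contagious), pre-symptomatic (relative rate r_p),
  then with probability p_c a clinical course (rate 1) or otherwise a
  sub-clinical one (rate r_sc).
"""

from __future__ import annotations

import csv
import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import isotonic_regression

from .substrate import WeightedContactGraph

__all__ = [
    "SimpleModelParams",
    "CovidParams",
    "InfectionEvent",
    "InfectionEventLog",
    "RunSummary",
    "simulate_simple",
    "simulate_runs",
    "child_seed",
    "estimate_r0",
    "calibrate_beta",
    "write_logs",
    "read_logs",
]

#: Table of canonical model presets: (mu_E, eta_E, mu_I, eta_I); mu_E None = SIR.
_PRESETS: dict[str, tuple[float | None, float, float, float]] = {
    "SIR": (None, 1.0, 0.25, 1.0),
    "SEIRe1": (1.0, 1.0, 1.0, 1.0),
    "SEIRe4": (0.25, 1.0, 1.0, 1.0),
    "SEIRi4": (1.0, 1.0, 0.25, 1.0),
    "SEIRe1v025": (1.0, 0.25, 1.0, 0.25),
    "SEIRe4v025": (0.25, 0.25, 1.0, 0.25),
    "SEIRi4v025": (1.0, 0.25, 0.25, 0.25),
}


@dataclass(frozen=True)
class SimpleModelParams:
    """SIR / SEIR parameters: rates mu_X = 1/mean duration, dispersion eta_X."""

    model_kind: str
    beta: float = 1.0
    mu_I: float = 0.25
    mu_E: float | None = None
    eta_E: float = 1.0
    eta_I: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.mu_I <= 0:
            raise ValueError("mu_I must be > 0")
        if self.mu_E is not None and self.mu_E <= 0:
            raise ValueError("mu_E must be > 0")
        for eta in (self.eta_E, self.eta_I):
            if not 0 < eta <= 1:
                raise ValueError("eta must be in (0, 1]")

    @classmethod
    def preset(cls, model_kind: str, beta: float = 1.0) -> "SimpleModelParams":
        """Canonical parameters for a named model variant."""
        if model_kind not in _PRESETS:
            raise ValueError(
                f"unknown model {model_kind!r}; known: {sorted(_PRESETS)}"
            )
        mu_E, eta_E, mu_I, eta_I = _PRESETS[model_kind]
        return cls(
            model_kind=model_kind,
            beta=beta,
            mu_I=mu_I,
            mu_E=mu_E,
            eta_E=eta_E,
            eta_I=eta_I,
        )

    def with_beta(self, beta: float) -> "SimpleModelParams":
        return SimpleModelParams(
            self.model_kind, beta, self.mu_I, self.mu_E, self.eta_E, self.eta_I
        )


@dataclass(frozen=True)
class CovidParams:
    """Multi-stage COVID-like model; stage durations as mean +/- std (days)."""

    beta: float = 1.0
    tau_E: float = 4.0
    sigma_E: float = 2.3
    tau_p: float = 1.8
    sigma_p: float = 1.8
    tau_I: float = 5.0
    sigma_I: float = 2.0
    p_c: float = 0.5
    r_p: float = 0.55
    r_sc: float = 0.55
    model_kind: str = "COVID"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for name in ("tau_E", "sigma_E", "tau_p", "sigma_p", "tau_I", "sigma_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_c", "r_p", "r_sc"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def with_beta(self, beta: float) -> "CovidParams":
        return CovidParams(
            beta,
            self.tau_E,
            self.sigma_E,
            self.tau_p,
            self.sigma_p,
            self.tau_I,
            self.sigma_I,
            self.p_c,
            self.r_p,
            self.r_sc,
        )


@dataclass(slots=True)
class InfectionEvent:
    """One infection: who got infected, when, by whom, through which channel."""

    time: float
    infectee: str
    attribution: dict[str, float]
    mechanism: str  # link | triad | threshold


@dataclass
class InfectionEventLog:
    """All infection events of one stochastic realization."""

    run_id: int
    seed_node: str | tuple[str, ...]
    events: list[InfectionEvent] = field(default_factory=list)
    stage_history: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def seeds(self) -> tuple[str, ...]:
        s = self.seed_node
        return (s,) if isinstance(s, str) else tuple(s)

    def n_ever_infected(self) -> int:
        return len(self.seeds()) + len(self.events)


@dataclass(frozen=True)
class RunSummary:
    run_id: int
    seed_node: str | tuple[str, ...]
    final_attack_rate: float
    end_time: float


def gamma_duration(rng: np.random.Generator, mean: float, std: float) -> float:
    """Gamma draw parameterized by mean and std: shape (mean/std)^2."""
    shape = (mean / std) ** 2
    scale = std * std / mean
    return float(rng.gamma(shape, scale))


def child_seed(base: int | Sequence[int], k: int) -> list[int]:
    """Flat per-run seed stream derived from a root seed and a run index."""
    if isinstance(base, (int, np.integer)):
        return [int(base), k]
    return [int(b) for b in base] + [k]


def _resolve_seeds(
    graph: WeightedContactGraph,
    seed_node: str | Sequence[str],
    rng: np.random.Generator,
) -> list[int]:
    if isinstance(seed_node, str):
        if seed_node == "random":
            return [int(rng.integers(graph.n_nodes))]
        if seed_node not in graph.index:
            raise ValueError(f"seed node {seed_node!r} not in graph")
        return [graph.index[seed_node]]
    idxs = []
    for s in seed_node:
        if s not in graph.index:
            raise ValueError(f"seed node {s!r} not in graph")
        idxs.append(graph.index[s])
    if not idxs:
        raise ValueError("empty seed collection")
    return idxs


def simulate_simple(
    graph: WeightedContactGraph,
    params: SimpleModelParams | CovidParams,
    seed_node: str | Sequence[str] = "random",
    rng_seed: int | Sequence[int] = 0,
    run_id: int = 0,
) -> tuple[InfectionEventLog, RunSummary]:
    """One exact event-driven realization on a weighted graph.

    Returns the infection-event log (every non-seed infection with its
    attribution and timestamp, plus per-node stage entry times) and a
    summary with the final attack rate (fraction ever infected, seed
    included) and the process end time.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(rng_seed)
    adj = graph.adjacency()
    nodes = graph.nodes
    beta = params.beta

    susceptible = np.ones(graph.n_nodes, dtype=bool)
    log = InfectionEventLog(run_id=run_id, seed_node=seed_node)
    heap: list[tuple[float, int, int, int]] = []
    seq = 0
    end_time = 0.0

    def schedule_windows(u: int, windows: list[tuple[float, float, float]]) -> None:
        """Push transmission candidates for infectious windows (start, dur, r)."""
        nonlocal seq
        nbrs, wts = adj[u]
        if len(nbrs) == 0 or beta == 0:
            return
        for start, dur, r in windows:
            rate = r * beta
            if rate <= 0 or dur <= 0:
                continue
            delays = rng.exponential(1.0, size=len(nbrs)) / (rate * wts)
            for k in np.flatnonzero(delays < dur):
                heapq.heappush(heap, (start + delays[k], seq, int(nbrs[k]), u))
                seq += 1

    def infect(u: int, t: float) -> None:
        nonlocal end_time
        susceptible[u] = False
        uid = nodes[u]
        hist: list[tuple[str, float]] = []
        if isinstance(params, CovidParams):
            t_E = gamma_duration(rng, params.tau_E, params.sigma_E)
            t_p = gamma_duration(rng, params.tau_p, params.sigma_p)
            t_I = gamma_duration(rng, params.tau_I, params.sigma_I)
            clinical = rng.random() < params.p_c
            r_last = 1.0 if clinical else params.r_sc
            hist = [
                ("E", t),
                ("P", t + t_E),
                ("Ic" if clinical else "Isc", t + t_E + t_p),
                ("R", t + t_E + t_p + t_I),
            ]
            windows = [
                (t + t_E, t_p, params.r_p),
                (t + t_E + t_p, t_I, r_last),
            ]
            recovery = t + t_E + t_p + t_I
        elif params.mu_E is None:  # SIR
            t_I = gamma_duration(rng, 1.0 / params.mu_I, params.eta_I / params.mu_I)
            hist = [("I", t), ("R", t + t_I)]
            windows = [(t, t_I, 1.0)]
            recovery = t + t_I
        else:  # SEIR
            t_E = gamma_duration(rng, 1.0 / params.mu_E, params.eta_E / params.mu_E)
            t_I = gamma_duration(rng, 1.0 / params.mu_I, params.eta_I / params.mu_I)
            hist = [("E", t), ("I", t + t_E), ("R", t + t_E + t_I)]
            windows = [(t + t_E, t_I, 1.0)]
            recovery = t + t_E + t_I
        log.stage_history[uid] = hist
        end_time = max(end_time, recovery)
        schedule_windows(u, windows)

    for s in _resolve_seeds(graph, seed_node, rng):
        infect(s, 0.0)
    if isinstance(seed_node, str) and seed_node == "random":
        # record the realized seed for the summary
        realized = tuple(uid for uid, h in log.stage_history.items())
        log.seed_node = realized[0] if len(realized) == 1 else realized

    while heap:
        t, _, target, source = heapq.heappop(heap)
        if not susceptible[target]:
            continue
        log.events.append(
            InfectionEvent(
                time=t,
                infectee=nodes[target],
                attribution={nodes[source]: 1.0},
                mechanism="link",
            )
        )
        infect(target, t)

    n_inf = log.n_ever_infected()
    summary = RunSummary(
        run_id=run_id,
        seed_node=log.seed_node,
        final_attack_rate=n_inf / graph.n_nodes,
        end_time=end_time,
    )
    return log, summary


def simulate_runs(
    graph: WeightedContactGraph,
    params: SimpleModelParams | CovidParams,
    n_runs: int,
    rng_seed: int,
    seed_node: str | Sequence[str] = "random",
) -> tuple[list[InfectionEventLog], list[RunSummary]]:
    """Independent realizations; run *k* uses the stream ``[rng_seed, k]``."""
    logs, summaries = [], []
    for k in range(n_runs):
        log, summ = simulate_simple(
            graph, params, seed_node=seed_node, rng_seed=child_seed(rng_seed, k), run_id=k
        )
        logs.append(log)
        summaries.append(summ)
    return logs, summaries


def estimate_r0(
    graph: WeightedContactGraph,
    params: SimpleModelParams | CovidParams,
    beta: float,
    n_runs: int,
    rng_seed: int | Sequence[int],
) -> float:
    """Monte-Carlo basic reproduction number.

    Each run starts from one uniformly random seed; the run's contribution is
    the number of nodes the seed directly infected before recovering (the
    transmission scheme only ever schedules infections inside the seed's
    infectious window, so every event attributed to the seed qualifies).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    p = params.with_beta(beta)
    total = 0
    for k in range(n_runs):
        log, _ = simulate_simple(
            graph, p, seed_node="random", rng_seed=child_seed(rng_seed, k), run_id=k
        )
        seed = log.seeds()[0]
        total += sum(1 for ev in log.events if seed in ev.attribution)
    return total / n_runs


def calibrate_beta(
    graph: WeightedContactGraph,
    params: SimpleModelParams | CovidParams,
    target_r0: float,
    beta_grid: Sequence[float] | None = None,
    runs_per_point: int = 1000,
    rng_seed: int | Sequence[int] = 0,
) -> float:
    """Transmission rate achieving a target R0 on this graph.

    Estimates R0 on a log-spaced beta grid, monotonizes the table by isotonic
    regression (Monte-Carlo noise can break monotonicity), and linearly
    interpolates the inverse map at ``target_r0``.
    """
    if beta_grid is None:
        beta_grid = np.geomspace(0.02, 20.0, 20)
    betas = np.asarray(sorted(beta_grid), dtype=float)
    r0s = np.array(
        [
            estimate_r0(graph, params, b, runs_per_point, rng_seed=child_seed(rng_seed, k))
            for k, b in enumerate(betas)
        ]
    )
    r0_iso = isotonic_regression(r0s).x
    lo, hi = float(r0_iso[0]), float(r0_iso[-1])
    if not lo <= target_r0 <= hi:
        raise ValueError(
            f"target R0={target_r0} outside achievable range [{lo:.4g}, {hi:.4g}] "
            "on this grid/graph"
        )
    return float(np.interp(target_r0, r0_iso, betas))


# --- log serialization -----------------------------------------------------


def write_logs(
    logs: Iterable[InfectionEventLog],
    summaries: Iterable[RunSummary],
    events_path: str | Path,
    summary_path: str | Path,
) -> None:
    """JSON-lines events (one infection per line) + CSV run summaries."""
    with open(events_path, "w") as fh:
        for log in logs:
            for ev in log.events:
                fh.write(
                    json.dumps(
                        {
                            "run": log.run_id,
                            "t": ev.time,
                            "infectee": ev.infectee,
                            "attribution": ev.attribution,
                            "mechanism": ev.mechanism,
                        }
                    )
                    + "\n"
                )
    with open(summary_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["run_id", "seed_node", "final_attack_rate", "end_time"])
        for s in summaries:
            seed = s.seed_node if isinstance(s.seed_node, str) else "|".join(s.seed_node)
            writer.writerow(
                [s.run_id, seed, repr(float(s.final_attack_rate)), repr(float(s.end_time))]
            )


def read_logs(
    events_path: str | Path, summary_path: str | Path
) -> tuple[list[InfectionEventLog], list[RunSummary]]:
    """Inverse of :func:`write_logs` (stage histories are not round-tripped)."""
    summaries: list[RunSummary] = []
    with open(summary_path, newline="") as fh:
        for row in csv.DictReader(fh):
            seed: str | tuple[str, ...] = row["seed_node"]
            if "|" in seed:
                seed = tuple(seed.split("|"))
            summaries.append(
                RunSummary(
                    run_id=int(row["run_id"]),
                    seed_node=seed,
                    final_attack_rate=float(row["final_attack_rate"]),
                    end_time=float(row["end_time"]),
                )
            )
    logs = {s.run_id: InfectionEventLog(run_id=s.run_id, seed_node=s.seed_node) for s in summaries}
    with open(events_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            logs[rec["run"]].events.append(
                InfectionEvent(
                    time=rec["t"],
                    infectee=rec["infectee"],
                    attribution=rec["attribution"],
                    mechanism=rec["mechanism"],
                )
            )
    ordered = [logs[s.run_id] for s in summaries]
    for log in ordered:
        log.events.sort(key=lambda e: e.time)
    return ordered, summaries
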