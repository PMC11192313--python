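"""Comparison of infection patterns across models, parameters and mechanisms.

The central quantity is the cosine similarity between two pattern matrices,
computed on the row-major flattening of the dense matrices over the shared
node index:

    cs(v, w) = (v . w) / (||v|| ||w||)

Since pattern entries are non-negative, cs lies in [0, 1].  On top of it the
module orchestrates the standard experiment designs: pairwise similarity of
several calibrated models (optionally conditioned on a final attack-rate
window), and time-matched comparison of a high-R0 reference pattern C_ref(t)
against the final patterns of slower processes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .complex_models import SimplicialParams, ThresholdParams, simulate_complex_runs
from .patterns import (
    InfectionPattern,
    NodeIndices,
    attack_rate_mode,
    build_infection_pattern,
    time_pattern_curve,
    write_pattern,
)
from .simple_models import (
    CovidParams,
    InfectionEventLog,
    RunSummary,
    SimpleModelParams,
    calibrate_beta,
    child_seed,
    simulate_simple,
    write_logs,
)
from .substrate import WeightedContactGraph, WeightedHypergraph
from .synthetic import SchoolLikeSpec, generate_school_like_events

__all__ = [
    "SimilarityMatrix",
    "ModelCondition",
    "ExperimentConfig",
    "cosine_similarity",
    "rank_agreement",
    "run_condition",
    "cross_condition_similarity",
    "time_matched_similarity",
    "TimeMatchedResult",
    "match_attack_rate",
]

AnyParams = SimpleModelParams | CovidParams | SimplicialParams | ThresholdParams


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise cosine-similarity matrix with condition labels."""

    labels: list[str]
    values: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass(frozen=True)
class ModelCondition:
    """One experimental condition: a model with either fixed or calibrated beta."""

    name: str
    params: AnyParams
    target_r0: float | None = None
    beta_grid: Sequence[float] | None = None
    runs_per_point: int = 1000


@dataclass
class ExperimentConfig:
    """A full comparison experiment over one substrate."""

    substrate: WeightedContactGraph | WeightedHypergraph | SchoolLikeSpec
    conditions: list[ModelCondition]
    n_runs: int = 1000
    attack_window: tuple[float, float] | None = None
    attempt_factor: int = 100
    time_grid: Sequence[float] | None = None
    rng_seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("need at least one condition")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def cosine_similarity(p1: InfectionPattern, p2: InfectionPattern) -> float:
    """Cosine similarity of two patterns over the same node index, in [0, 1]."""
    if p1.index != p2.index:
        raise ValueError("patterns are defined over different node indices")
    dot = 0.0
    for k, v in p1.entries.items():
        w = p2.entries.get(k)
        if w is not None:
            dot += v * w
    n1 = math.sqrt(sum(v * v for v in p1.entries.values()))
    n2 = math.sqrt(sum(v * v for v in p2.entries.values()))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero pattern")
    return dot / (n1 * n2)


def rank_agreement(idx1: NodeIndices, idx2: NodeIndices, which: str = "spreader") -> float:
    """Kendall rank correlation (tau-b, midrank ties) of a node index."""
    if which not in ("spreader", "receiver"):
        raise ValueError("which must be 'spreader' or 'receiver'")
    d1, d2 = getattr(idx1, which), getattr(idx2, which)
    if set(d1) != set(d2):
        raise ValueError("node sets differ")
    nodes = sorted(d1)
    x = np.array([d1[n] for n in nodes])
    y = np.array([d2[n] for n in nodes])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant index")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def _as_graph(sub: WeightedContactGraph | WeightedHypergraph) -> WeightedContactGraph:
    return sub.base if isinstance(sub, WeightedHypergraph) else sub


def _simulate_one(
    substrate: WeightedContactGraph | WeightedHypergraph,
    params: AnyParams,
    rng_seed,
    run_id: int,
) -> tuple[InfectionEventLog, RunSummary]:
    if isinstance(params, SimplicialParams):
        if not isinstance(substrate, WeightedHypergraph):
            raise TypeError("simplicial contagion needs a WeightedHypergraph")
        from .complex_models import simulate_simplicial

        return simulate_simplicial(substrate, params, rng_seed=rng_seed, run_id=run_id)
    if isinstance(params, ThresholdParams):
        from .complex_models import simulate_threshold

        return simulate_threshold(_as_graph(substrate), params, rng_seed=rng_seed, run_id=run_id)
    return simulate_simple(_as_graph(substrate), params, rng_seed=rng_seed, run_id=run_id)


def run_condition(
    substrate: WeightedContactGraph | WeightedHypergraph,
    cond: ModelCondition,
    n_runs: int,
    rng_seed: int | Sequence[int],
    attack_window: tuple[float, float] | None = None,
    attempt_factor: int = 100,
) -> tuple[list[InfectionEventLog], list[RunSummary], AnyParams]:
    """Calibrate (if asked), then simulate until ``n_runs`` usable runs exist.

    With an attack-rate window, runs are resampled until the window quota is
    met or ``attempt_factor * n_runs`` attempts are exhausted (then an error
    reports the achieved count).  Returns the (possibly recalibrated) params.
    """
    params = cond.params
    if cond.target_r0 is not None:
        if isinstance(params, (SimplicialParams, ThresholdParams)):
            raise ValueError("R0 calibration is defined for simple-contagion models")
        beta = calibrate_beta(
            _as_graph(substrate),
            params,
            cond.target_r0,
            beta_grid=cond.beta_grid,
            runs_per_point=cond.runs_per_point,
            rng_seed=child_seed(rng_seed, 0),
        )
        params = params.with_beta(beta)

    logs: list[InfectionEventLog] = []
    summaries: list[RunSummary] = []
    max_attempts = attempt_factor * n_runs if attack_window else n_runs
    attempt = 0
    while len(logs) < n_runs and attempt < max_attempts:
        log, summ = _simulate_one(
            substrate, params, rng_seed=child_seed(rng_seed, 1 + attempt), run_id=attempt
        )
        attempt += 1
        if attack_window is not None:
            lo, hi = attack_window
            if not lo <= summ.final_attack_rate <= hi:
                continue
        logs.append(log)
        summaries.append(summ)
    if len(logs) < n_runs:
        raise RuntimeError(
            f"condition {cond.name!r}: only {len(logs)}/{n_runs} runs fell in "
            f"attack-rate window {attack_window} after {attempt} attempts"
        )
    return logs, summaries, params


def cross_condition_similarity(cfg: ExperimentConfig) -> SimilarityMatrix:
    """Pairwise cosine similarity of the patterns of all conditions.

    Builds the substrate (generating events first if given a synthetic spec),
    runs every condition with a per-condition child seed, optionally
    conditions each on the common attack-rate window, builds the patterns and
    fills the symmetric similarity matrix.  When ``cfg.outdir`` is set, all
    logs, patterns, the matrix and a manifest are persisted there.
    """
    substrate = cfg.substrate
    if isinstance(substrate, SchoolLikeSpec):
        from .substrate import build_weighted_hypergraph

        substrate = build_weighted_hypergraph(generate_school_like_events(substrate))
    graph = _as_graph(substrate)

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    pats: list[InfectionPattern] = []
    for c_idx, cond in enumerate(cfg.conditions):
        logs, summaries, _used = run_condition(
            substrate,
            cond,
            cfg.n_runs,
            rng_seed=child_seed(cfg.rng_seed, c_idx),
            attack_window=cfg.attack_window,
            attempt_factor=cfg.attempt_factor,
        )
        pat = build_infection_pattern(logs, graph.index)
        pats.append(pat)
        if outdir:
            write_logs(
                logs,
                summaries,
                outdir / f"{cond.name}.events.jsonl",
                outdir / f"{cond.name}.summaries.csv",
            )
            write_pattern(pat, outdir / f"{cond.name}.pattern.tsv")

    n = len(pats)
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = cosine_similarity(pats[a], pats[b])
    matrix = SimilarityMatrix(labels=[c.name for c in cfg.conditions], values=values)
    if outdir:
        with open(outdir / "similarity.csv", "w") as fh:
            fh.write("," + ",".join(matrix.labels) + "\n")
            for lab, row in zip(matrix.labels, values):
                fh.write(lab + "," + ",".join(f"{v:.6f}" for v in row) + "\n")
        _write_manifest(cfg, outdir)
    return matrix


@dataclass
class TimeMatchedResult:
    """Similarity-vs-time curves of a reference C_ref(t) against final patterns."""

    times: np.ndarray
    curves: dict[str, np.ndarray]  # per test condition: cs(C_ref(t), C_test)
    ref_mode_curve: np.ndarray  # non-zero mode of the time-t attack rates
    test_modes: dict[str, float | None]  # final non-zero attack-rate modes
    argmax_times: dict[str, float]
    crossing_times: dict[str, float | None]


def time_matched_similarity(
    substrate: WeightedContactGraph | WeightedHypergraph,
    ref_cond: ModelCondition,
    test_conds: Sequence[ModelCondition],
    time_grid: Sequence[float],
    n_runs: int = 1000,
    rng_seed: int = 0,
    bin_width: float = 0.02,
    zero_cutoff: float = 0.1,
) -> TimeMatchedResult:
    """Compare a fast reference process in time with slower final patterns.

    For each grid time t, cs(C_ref(t), C_test) is computed for every test
    condition; the result also carries the time course of the reference's
    non-zero attack-rate mode and each test condition's final mode, whose
    crossing predicts where the similarity curve peaks.
    """
    grid = np.asarray(list(time_grid), dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("time_grid must be sorted ascending")
    graph = _as_graph(substrate)
    n_nodes = graph.n_nodes

    ref_logs, _, _ = run_condition(
        substrate, ref_cond, n_runs, rng_seed=child_seed(rng_seed, 0)
    )
    ref_curve = time_pattern_curve(ref_logs, graph.index, grid)

    ref_mode = np.empty(len(grid))
    for gi, t in enumerate(grid):
        rates = [
            (1 + sum(1 for ev in log.events if ev.time <= t)) / n_nodes
            for log in ref_logs
        ]
        m = attack_rate_mode(rates, bin_width=bin_width, zero_cutoff=zero_cutoff)
        ref_mode[gi] = math.nan if m is None else m

    curves: dict[str, np.ndarray] = {}
    test_modes: dict[str, float | None] = {}
    argmax_times: dict[str, float] = {}
    crossing_times: dict[str, float | None] = {}
    for k, cond in enumerate(test_conds):
        logs, summaries, _ = run_condition(
            substrate, cond, n_runs, rng_seed=child_seed(rng_seed, k + 1)
        )
        pat = build_infection_pattern(logs, graph.index)
        sim = np.array(
            [
                cosine_similarity(cp, pat) if cp.entries else 0.0
                for cp in ref_curve
            ]
        )
        curves[cond.name] = sim
        mode = attack_rate_mode(summaries, bin_width=bin_width, zero_cutoff=zero_cutoff)
        test_modes[cond.name] = mode
        argmax_times[cond.name] = float(grid[int(np.argmax(sim))])
        if mode is None:
            crossing_times[cond.name] = None
        else:
            reached = np.flatnonzero(~np.isnan(ref_mode) & (ref_mode >= mode))
            crossing_times[cond.name] = float(grid[reached[0]]) if len(reached) else None
    return TimeMatchedResult(
        times=grid,
        curves=curves,
        ref_mode_curve=ref_mode,
        test_modes=test_modes,
        argmax_times=argmax_times,
        crossing_times=crossing_times,
    )


def match_attack_rate(
    hg: WeightedHypergraph,
    beta_tri: float,
    mu_I: float,
    target_attack_rate: float,
    beta_link_bounds: tuple[float, float] = (1e-3, 50.0),
    n_runs: int = 200,
    rng_seed: int = 0,
    n_iter: int = 12,
) -> SimplicialParams:
    """Bisect beta_link (at fixed beta_tri) to hit a mean final attack rate.

    Used to construct simplicial parameter pairs with different link/triad
    event mixes but the same epidemic size.
    """

    def mean_attack(beta_link: float, salt: int) -> float:
        params = SimplicialParams(beta_link=beta_link, beta_tri=beta_tri, mu_I=mu_I)
        _, summaries = simulate_complex_runs(
            hg, params, n_runs, rng_seed=rng_seed + salt
        )
        return float(np.mean([s.final_attack_rate for s in summaries]))

    lo, hi = beta_link_bounds
    if mean_attack(lo, 1) > target_attack_rate:
        return SimplicialParams(beta_link=lo, beta_tri=beta_tri, mu_I=mu_I)
    if mean_attack(hi, 2) < target_attack_rate:
        raise ValueError("target attack rate unreachable within beta_link bounds")
    for it in range(n_iter):
        mid = math.sqrt(lo * hi)
        if mean_attack(mid, 3 + it) < target_attack_rate:
            lo = mid
        else:
            hi = mid
    return SimplicialParams(beta_link=math.sqrt(lo * hi), beta_tri=beta_tri, mu_I=mu_I)


def _write_manifest(cfg: ExperimentConfig, outdir: Path) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {"__type__": type(obj).__name__, **dataclasses.asdict(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        return repr(obj)

    manifest = {
        "conditions": [enc(c) for c in cfg.conditions],
        "n_runs": cfg.n_runs,
        "attack_window": cfg.attack_window,
        "rng_seed": cfg.rng_seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=enc)
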