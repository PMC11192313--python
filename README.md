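# epipattern

Infection patterns of simple and complex contagion processes on weighted
contact networks.

When a contagion process — an infectious disease, a piece of information, a
social behaviour — spreads over a contact network, it leaves a *signature*:
some links carry transmissions often, others almost never. `epipattern`
computes this signature, the **infection pattern** `C`, whose entry `C_ij`
is the probability (averaged over stochastic realizations) that node *i*
directly infected node *j*, and provides the machinery to compare these
patterns across models, parameters, and contagion mechanisms:

- **Substrates.** Time-resolved proximity records (`t i j` lines, as in the
  public SocioPatterns datasets) are aggregated into weighted graphs
  (`W_ij = n_ij / n_max`, where `n_ij` counts the 20-second slices the pair
  spent in contact) and weighted hypergraphs whose size-3 hyperedges are the
  triads found in the per-timestamp snapshot graphs (`W^Δ_ijk = n_ijk /
  n^(2)_max`). A synthetic generator emulates a primary school: classes,
  heavy-tailed contact counts, simultaneous triangles, and correlated
  link/triad weights.
- **Simple contagion.** Exact event-driven SIR, Markovian and non-Markovian
  (gamma-duration) SEIR variants, and a multi-stage COVID-like model; a node
  in an infectious stage with relative transmissibility `r` transmits along
  each link as an exponential clock of rate `r·β·W_ij`. Includes Monte-Carlo
  `R0` estimation and calibration of `β` to a target `R0` by interpolating a
  monotonized `(β, R̂0)` table.
- **Complex contagion.** A simplicial SIR on hypergraphs (extra hazard
  `β_Δ·W^Δ_ikl` on a susceptible node when both other triad members are
  infectious; such events are attributed ½/½ to the two infectors) and a
  weighted threshold model (deterministic infection once the infectious
  fraction of a node's total link weight strictly exceeds `θ`; attribution
  proportional to link weights).
- **Patterns and comparison.** Pattern matrices `C` and their time-resolved
  versions `C(t)`, spreader/receiver indices `s_i = Σ_j C_ij`,
  `r_i = Σ_j C_ji`, the link/triad mechanism split `C = C₁ + C₂`,
  attack-rate conditioning and mode estimation, cosine similarity between
  flattened patterns, Kendall rank agreement of node indices, and
  ready-made experiment drivers (cross-condition similarity matrices,
  time-matched comparison of a fast reference process against slower ones).

## Worked example

```python
import numpy as np
from epipattern import (
    SchoolLikeSpec, generate_school_like_events, build_weighted_hypergraph,
    SimpleModelParams, simulate_runs, build_infection_pattern, node_indices,
    cosine_similarity,
)

spec = SchoolLikeSpec(n_groups=4, group_size=15, n_snapshots=600,
                      p_within=0.02, p_between=0.0005, p_gather=0.08,
                      weight_correlation=0.7, rng_seed=11)
hg = build_weighted_hypergraph(generate_school_like_events(spec))
g = hg.base
print(f"substrate: {g.n_nodes} nodes, {len(g.edges)} links, {len(hg.triads)} triads")

patterns = {}
for beta in (1.3, 2.6):
    params = SimpleModelParams(model_kind="SIR", beta=beta, mu_I=1.0)
    logs, summaries = simulate_runs(g, params, n_runs=500, rng_seed=0)
    pat = build_infection_pattern(logs, g.index)
    attack = np.mean([s.final_attack_rate for s in summaries])
    print(f"SIR beta={beta}: mean attack rate {attack:.3f}, "
          f"sum of C = {pat.total():.3f}")
    patterns[beta] = pat

print(f"cosine similarity of the two patterns: "
      f"{cosine_similarity(patterns[1.3], patterns[2.6]):.4f}")
top = sorted(node_indices(patterns[2.6]).spreader.items(),
             key=lambda kv: -kv[1])[:3]
print("top spreaders:", ", ".join(f"{n} ({s:.2f})" for n, s in top))
```

Output:

```
substrate: 60 nodes, 757 links, 84 triads
SIR beta=1.3: mean attack rate 0.263, sum of C = 14.770
SIR beta=2.6: mean attack rate 0.678, sum of C = 39.664
cosine similarity of the two patterns: 0.9501
top spreaders: n55 (1.05), n30 (1.00), n50 (0.91)
```

Reading it: doubling the transmission rate more than doubles the epidemic
size (the sum of all `C` entries equals the mean number of non-seed
infections per run — a conservation law the test suite checks to 1e-9), yet
the two patterns point in almost the same direction (cosine 0.95): *which*
links carry the contagion is far more stable than *how much* contagion there
is. The spreader index ranks nodes by the expected number of neighbours they
infect per run.

A command-line interface mirrors the library (`epipattern generate`,
`build-substrate`, `simulate`, `calibrate`, `pattern`, `compare`,
`time-matched`); run `epipattern --help`.

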