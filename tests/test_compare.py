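"""Cosine similarity, rank agreement and experiment orchestration."""

import itertools
import math

import numpy as np
import pytest

from epipattern import (
    ExperimentConfig,
    InfectionPattern,
    ModelCondition,
    NodeIndices,
    SimpleModelParams,
    build_infection_pattern,
    calibrate_beta,
    cosine_similarity,
    cross_condition_similarity,
    make_toy_graph,
    rank_agreement,
    run_condition,
    shuffle_edge_weights,
    simulate_runs,
    time_matched_similarity,
)

IDX = {"a": 0, "b": 1, "c": 2, "d": 3}


def pat(entries, index=IDX):
    return InfectionPattern(entries=dict(entries), index=index, n_runs=1)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        p = pat({(0, 1): 0.3, (1, 2): 0.7})
        assert cosine_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        assert cosine_similarity(pat({(0, 1): 1.0}), pat({(2, 3): 1.0})) == 0.0

    def test_known_value_one_over_sqrt2(self):
        # vectors (1, 0) and (1, 1)
        p1 = pat({(0, 1): 1.0})
        p2 = pat({(0, 1): 1.0, (1, 2): 1.0})
        assert cosine_similarity(p1, p2) == pytest.approx(1 / math.sqrt(2))

    def test_zero_pattern_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            cosine_similarity(pat({}), pat({(0, 1): 1.0}))

    def test_mismatched_index_errors(self):
        with pytest.raises(ValueError, match="node indices"):
            cosine_similarity(pat({(0, 1): 1.0}), pat({(0, 1): 1.0}, index={"x": 0, "y": 1}))

    def test_scale_invariant(self):
        p1 = pat({(0, 1): 0.2, (2, 3): 0.4})
        p2 = pat({(0, 1): 0.1, (2, 3): 0.2})
        assert cosine_similarity(p1, p2) == pytest.approx(1.0)


def brute_force_kendall(d1, d2):
    nodes = sorted(d1)
    conc = disc = 0
    for a, b in itertools.combinations(nodes, 2):
        s = (d1[a] - d1[b]) * (d2[a] - d2[b])
        conc += s > 0
        disc += s < 0
    n_pairs = len(nodes) * (len(nodes) - 1) // 2
    return (conc - disc) / n_pairs


class TestRankAgreement:
    def ni(self, d):
        return NodeIndices(spreader=d, receiver=d)

    def test_identical_gives_one(self):
        d = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert rank_agreement(self.ni(d), self.ni(d)) == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        d1 = {"a": 3.0, "b": 2.0, "c": 1.0}
        d2 = {"a": 1.0, "b": 2.0, "c": 3.0}
        assert rank_agreement(self.ni(d1), self.ni(d2)) == pytest.approx(-1.0)

    def test_single_swap_matches_brute_force(self):
        d1 = {"a": 3.0, "b": 2.0, "c": 1.0}
        d2 = {"a": 3.0, "b": 1.0, "c": 2.0}
        expected = brute_force_kendall(d1, d2)  # = 1/3
        assert expected == pytest.approx(1 / 3)
        assert rank_agreement(self.ni(d1), self.ni(d2)) == pytest.approx(expected)

    def test_constant_index_errors(self):
        with pytest.raises(ValueError, match="constant"):
            rank_agreement(self.ni({"a": 1.0, "b": 1.0}), self.ni({"a": 1.0, "b": 2.0}))

    def test_receiver_selector_and_node_set_check(self):
        n1 = NodeIndices(spreader={"a": 1.0}, receiver={"a": 1.0, "b": 0.5})
        n2 = NodeIndices(spreader={"a": 1.0}, receiver={"a": 0.5, "b": 1.0})
        with pytest.raises(ValueError):
            rank_agreement(n1, n2, which="degree")
        assert rank_agreement(n1, n2, which="receiver") == pytest.approx(-1.0)


class TestCrossConditionSimilarity:
    def test_matrix_invariants_and_persistence(self, school_small, tmp_path):
        cfg = ExperimentConfig(
            substrate=school_small,
            conditions=[
                ModelCondition("sir_lo", SimpleModelParams(model_kind="SIR", beta=1.0, mu_I=1.0)),
                ModelCondition("sir_hi", SimpleModelParams(model_kind="SIR", beta=2.5, mu_I=1.0)),
            ],
            n_runs=80,
            rng_seed=1,
            outdir=tmp_path / "exp",
        )
        m = cross_condition_similarity(cfg)
        assert m.labels == ["sir_lo", "sir_hi"]
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        assert np.all(m.values >= 0) and np.all(m.values <= 1)
        for name in ("similarity.csv", "manifest.json", "sir_lo.pattern.tsv", "sir_lo.events.jsonl"):
            assert (tmp_path / "exp" / name).exists()

    def test_zero_beta_condition_errors(self, school_small):
        cfg = ExperimentConfig(
            substrate=school_small,
            conditions=[
                ModelCondition("dead1", SimpleModelParams(model_kind="SIR", beta=0.0)),
                ModelCondition("dead2", SimpleModelParams(model_kind="SIR", beta=0.0)),
            ],
            n_runs=10,
            rng_seed=2,
        )
        with pytest.raises(ValueError, match="all-zero"):
            cross_condition_similarity(cfg)

    def test_self_similarity_converges_with_runs(self, school_small):
        """Two independent estimates of the same pattern approach cs=1."""
        g = school_small.base
        p = SimpleModelParams(model_kind="SIR", beta=2.0, mu_I=1.0)

        def cs_at(n):
            l1, _ = simulate_runs(g, p, n, rng_seed=100)
            l2, _ = simulate_runs(g, p, n, rng_seed=200)
            return cosine_similarity(
                build_infection_pattern(l1, g.index), build_infection_pattern(l2, g.index)
            )

        lo, hi = cs_at(100), cs_at(600)
        assert hi > lo

    def test_window_quota_failure_reports_count(self, school_small):
        cond = ModelCondition("sir", SimpleModelParams(model_kind="SIR", beta=2.0, mu_I=1.0))
        with pytest.raises(RuntimeError, match="runs fell in"):
            run_condition(
                school_small.base,
                cond,
                n_runs=50,
                rng_seed=3,
                attack_window=(0.985, 0.999),  # between 29/30 and 30/30: empty
                attempt_factor=2,
            )


class TestTimeMatched:
    def test_contract_and_curve_shapes(self, school_small):
        sir = lambda b: SimpleModelParams(model_kind="SIR", beta=b, mu_I=1.0)
        grid = [1.0, 2.0, 4.0, 8.0]
        res = time_matched_similarity(
            school_small,
            ModelCondition("ref", sir(3.0)),
            [ModelCondition("lo", sir(1.5))],
            grid,
            n_runs=150,
            rng_seed=5,
        )
        curve = res.curves["lo"]
        assert curve.shape == (4,)
        assert np.all((curve >= 0) & (curve <= 1))
        assert res.argmax_times["lo"] in grid
        assert res.test_modes["lo"] is None or 0 < res.test_modes["lo"] <= 1

    def test_unsorted_grid_errors(self, school_small):
        sir = SimpleModelParams(model_kind="SIR", beta=2.0, mu_I=1.0)
        with pytest.raises(ValueError, match="sorted"):
            time_matched_similarity(
                school_small,
                ModelCondition("r", sir),
                [ModelCondition("t", sir)],
                [2.0, 1.0],
                n_runs=10,
                rng_seed=6,
            )

    def test_later_mode_never_earlier_argmax(self, school_medium):
        """Qualitative Fig-4 ordering: larger final mode => later-or-equal peak."""
        sir = lambda b: SimpleModelParams(model_kind="SIR", beta=b, mu_I=1.0)
        grid = np.arange(0.5, 10.01, 0.5)
        res = time_matched_similarity(
            school_medium,
            ModelCondition("ref", sir(3.0)),
            [ModelCondition("slow", sir(1.0)), ModelCondition("fast", sir(2.0))],
            grid,
            n_runs=400,
            rng_seed=7,
            bin_width=0.05,
            zero_cutoff=0.15,
        )
        if res.test_modes["slow"] is not None and res.test_modes["fast"] is not None:
            assert res.test_modes["slow"] <= res.test_modes["fast"]
            assert res.argmax_times["slow"] <= res.argmax_times["fast"] + 0.5


class TestModelRobustness:
    def test_cross_model_similarity_beats_weight_shuffled_null(self, school_small):
        """Patterns of different simple models at equal R0 are closer to each
        other than the SIR pattern is to one on a weight-shuffled substrate."""
        g = school_small.base
        target = 2.0
        grid = np.geomspace(0.2, 30.0, 12)
        pats = {}
        for kind in ("SIR", "SEIRe4", "SEIRi4v025"):
            params = SimpleModelParams.preset(kind)
            beta = calibrate_beta(g, params, target, beta_grid=grid, runs_per_point=150, rng_seed=41)
            logs, _ = simulate_runs(g, params.with_beta(beta), 400, rng_seed=42)
            pats[kind] = build_infection_pattern(logs, g.index)
        cross = min(
            cosine_similarity(pats[a], pats[b])
            for a, b in itertools.combinations(pats, 2)
        )
        null_graph = shuffle_edge_weights(g, rng_seed=43)
        beta_sir = calibrate_beta(
            null_graph, SimpleModelParams.preset("SIR"), target, beta_grid=grid, runs_per_point=150, rng_seed=44
        )
        null_logs, _ = simulate_runs(
            null_graph, SimpleModelParams.preset("SIR", beta=beta_sir), 400, rng_seed=45
        )
        null_pat = build_infection_pattern(null_logs, g.index)
        assert cross > cosine_similarity(pats["SIR"], null_pat)
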