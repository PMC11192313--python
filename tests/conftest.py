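"""Shared fixtures: synthetic substrates generated once per session."""

import pytest

from epipattern import (
    SchoolLikeSpec,
    build_weighted_hypergraph,
    generate_school_like_events,
)


@pytest.fixture(scope="session")
def school_small():
    """30-node, 3-class substrate: fast enough for per-run oracle tests."""
    spec = SchoolLikeSpec(
        n_groups=3,
        group_size=10,
        n_snapshots=400,
        p_within=0.02,
        p_between=0.002,
        p_gather=0.05,
        weight_correlation=0.7,
        rng_seed=5,
    )
    return build_weighted_hypergraph(generate_school_like_events(spec))


@pytest.fixture(scope="session")
def school_medium():
    """60-node, 4-class substrate with crisp bimodal attack-rate behaviour."""
    spec = SchoolLikeSpec(
        n_groups=4,
        group_size=15,
        n_snapshots=600,
        p_within=0.02,
        p_between=0.0005,
        p_gather=0.08,
        weight_correlation=0.7,
        rng_seed=11,
    )
    return build_weighted_hypergraph(generate_school_like_events(spec))
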