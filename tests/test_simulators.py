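"""Evolvability and ERM simulators, analytic expectations, asymptotics."""

import math

import numpy as np
import pytest

from phylodepth import (
    EvolvabilityConfig,
    asymptotic_depth_check,
    evolvability_size_sample,
    evolvability_subtree_points,
    expected_cumulative,
    expected_nodes,
    make_balanced,
    make_caterpillar,
    mean_depth,
    node_depths,
    parse_newick,
    sackin_index,
    cumulative_branch_size,
    simulate_erm,
    simulate_evolvability,
    stats_table,
    topology_equal,
)


def test_config_validation():
    with pytest.raises(ValueError):
        EvolvabilityConfig(p=1.2, n_generations=3)
    with pytest.raises(ValueError):
        EvolvabilityConfig(p=0.5)  # no stopping rule
    with pytest.raises(ValueError):
        EvolvabilityConfig(p=0.5, n_generations=3, max_nodes=100)  # both
    with pytest.raises(ValueError):
        EvolvabilityConfig(p=0.5, n_generations=0)
    with pytest.raises(ValueError):
        EvolvabilityConfig(p=0.5, max_nodes=2)


@pytest.mark.parametrize("seed", [0, 1, 99])
def test_extreme_p_deterministic_topologies(seed):
    """p = 1 always the fully balanced tree; p = 0 always the caterpillar."""
    (bal,) = simulate_evolvability(
        EvolvabilityConfig(p=1.0, n_generations=3, seed=seed)
    )
    assert topology_equal(bal, make_balanced(3))
    assert bal.n_nodes == 15 and mean_depth(bal) == mean_depth(make_balanced(3))
    (cat,) = simulate_evolvability(
        EvolvabilityConfig(p=0.0, n_generations=3, seed=seed)
    )
    assert topology_equal(cat, make_caterpillar(4))
    assert cat.n_nodes == 7


def test_capable_flags_and_no_extinction():
    trees = simulate_evolvability(
        EvolvabilityConfig(p=0.3, n_generations=6, seed=4, replicates=5)
    )
    for tree in trees:
        assert all(n.capable is not None for n in tree)
        depths = node_depths(tree)
        deepest = max(depths.values())
        # never extinct: at least one capable leaf at the deepest level
        assert any(
            n.capable for n in tree if n.is_leaf and depths[n] == deepest
        )
        # only capable nodes ever branched
        assert all(n.capable for n in tree if not n.is_leaf)
        # strictly binary
        assert all(len(n.children) in (0, 2) for n in tree)


def test_max_nodes_stopping_completes_generation():
    (tree,) = simulate_evolvability(
        EvolvabilityConfig(p=0.7, max_nodes=50, seed=1)
    )
    assert tree.n_nodes >= 50
    depths = node_depths(tree)
    deepest = max(depths.values())
    n_before_last = sum(1 for d in depths.values() if d < deepest)
    assert n_before_last < 50  # the cap was first reached by the final generation


def test_expected_nodes_closed_forms():
    for n in range(0, 11):
        assert expected_nodes(n, 1.0) == 2 ** (n + 1) - 1
        assert expected_nodes(n, 0.0) == 2 * n + 1
    assert expected_nodes(5, 0.5) == pytest.approx(27.375)


@pytest.mark.parametrize("n", range(1, 9))
def test_expected_cumulative_deterministic_extremes(n):
    """At p = 1/0 the trees are deterministic, so E[C] must equal the C of
    the balanced/caterpillar tree measured by the shape statistics."""
    assert expected_cumulative(n, 1.0) == cumulative_branch_size(make_balanced(n))
    assert expected_cumulative(n, 0.0) == cumulative_branch_size(
        make_caterpillar(n + 1)
    )


def test_monte_carlo_matches_expectations():
    sample = evolvability_size_sample(0.5, 10, 3000, seed=2024)
    for col, expected in (
        ("A", expected_nodes(10, 0.5)),
        ("C", expected_cumulative(10, 0.5)),
    ):
        se = sample[col].std(ddof=1) / math.sqrt(len(sample))
        assert abs(sample[col].mean() - expected) < 3 * se


def test_tree_simulator_matches_size_sample_route():
    """The object-level simulator and the counts-only Monte Carlo are the
    same process: their A means agree with each other and the recurrence."""
    trees = simulate_evolvability(
        EvolvabilityConfig(p=0.4, n_generations=6, seed=77, replicates=400)
    )
    A = np.array([t.n_nodes for t in trees])
    expected = expected_nodes(6, 0.4)
    se = A.std(ddof=1) / math.sqrt(len(A))
    assert abs(A.mean() - expected) < 3 * se
    sample = evolvability_size_sample(0.4, 6, 400, seed=77)
    pooled_se = math.sqrt(se**2 + sample.A.var(ddof=1) / len(sample))
    assert abs(A.mean() - sample.A.mean()) < 3 * pooled_se


def test_asymmetric_event_frequency():
    sample = evolvability_size_sample(0.24, 10, 500, seed=9)
    frac = sample.asym_events.sum() / sample.branchings.sum()
    n = sample.branchings.sum()
    se = math.sqrt(0.24 * 0.76 / n)
    assert abs(frac - 0.76) < 3 * se


def test_subtree_points_equal_tree_route_exactly():
    """The vectorized (A, d) fast path reproduces, point for point, the
    subtree statistics of the object-level trees from the same seed."""
    A, d = evolvability_subtree_points(0.4, 5, 3, seed=9)
    trees = simulate_evolvability(
        EvolvabilityConfig(p=0.4, n_generations=5, seed=9, replicates=3)
    )
    table = stats_table(trees)
    fast = sorted(zip(A.tolist(), np.round(d, 10)))
    slow = sorted(zip(table.A.tolist(), np.round(table.d, 10)))
    assert fast == slow


def test_erm_small_cases():
    assert topology_equal(simulate_erm(2, seed=5), parse_newick("(A,B);"))
    assert topology_equal(simulate_erm(3, seed=5), parse_newick("((A,B),C);"))
    tree = simulate_erm(64, seed=5)
    assert tree.n_leaves == 64 and tree.n_nodes == 127
    with pytest.raises(ValueError):
        simulate_erm(1)


def test_erm_depth_grows_logarithmically():
    """Mean depth of ERM trees grows ~ ln A: quadrupling the leaf count
    multiplies d by about ln(511)/ln(127), nowhere near the linear factor 4."""

    def mean_d(L, seed0, reps=150):
        return np.mean(
            [
                float(mean_depth(simulate_erm(L, rng=np.random.default_rng([seed0, i]))))
                for i in range(reps)
            ]
        )

    ratio = mean_d(256, 11) / mean_d(64, 22)
    assert 1.1 < ratio < 1.6  # ln ratio = 1.29; linear growth would give 4


def test_evolvability_curve_between_envelopes():
    """Binned depth of p = 0.24 model trees sits strictly between the
    star and caterpillar reference curves."""
    from phylodepth import closed_form_depth, log_bin

    A, d = evolvability_subtree_points(0.24, 12, 200, seed=3)
    curve = log_bin((A, d), base=2.0, min_A=3)
    for _, row in curve.table.iterrows():
        lo = curve.min_A * curve.base ** row.k  # bin edges
        hi = curve.min_A * curve.base ** (row.k + 1)
        # star depth is increasing in A and caterpillar depth is increasing,
        # so the edges bound every point the bin can contain
        lower = (lo - 1) / lo
        upper = (hi**2 - 1) / (4 * hi)
        assert lower < row.mean_d < upper


def test_asymptotic_depth_ratio_converges():
    series = asymptotic_depth_check(0.5, 300)
    assert abs(series.ratio.iloc[-1] - 1 / math.log(1.5)) / (1 / math.log(1.5)) < 0.02
    # per-generation depth increment tends to 1 while ln A grows by ln z
    diffs = np.diff(series.d.to_numpy())
    assert diffs[-1] == pytest.approx(1.0, abs=1e-6)
    # ratio settles monotonically beyond the transient
    tail = series.ratio.to_numpy()[50:]
    assert np.all(np.abs(np.diff(tail)) < 0.01)
    with pytest.raises(ValueError):
        asymptotic_depth_check(1.0, 10)
    with pytest.raises(ValueError):
        asymptotic_depth_check(0.0, 10)


def test_replicates_reproducible_and_order_independent():
    trees_a = simulate_evolvability(
        EvolvabilityConfig(p=0.5, n_generations=5, seed=123, replicates=3)
    )
    trees_b = simulate_evolvability(
        EvolvabilityConfig(p=0.5, n_generations=5, seed=123, replicates=5)
    )
    for a, b in zip(trees_a, trees_b):
        assert topology_equal(a, b)
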