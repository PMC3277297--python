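"""Branching-process tree simulators and their analytic expectations.

Two generators:

* :func:`simulate_erm` — the Equal-Rates Markov null model: grow a binary
  tree by bifurcating a uniformly chosen leaf at each step; mean depth
  scales as ln A.

* :func:`simulate_evolvability` — the evolvability/robustness model.  The
  process starts from a single lineage able to diversify ("capable").  At
  each time step every capable leaf branches synchronously into two
  daughters; with probability ``p`` both daughters inherit the capability,
  and with probability ``1 - p`` exactly one daughter (chosen uniformly)
  stays capable while the other becomes permanently robust (incapable).
  ``p = 1`` deterministically yields the fully balanced binary tree,
  ``p = 0`` the caterpillar; intermediate ``p`` interpolates between the
  extreme depth-scaling curves with a long non-ERM transient before the
  asymptotic d ~ ln A regime.

Expectations.  With z = 1 + p the expected number of capable leaves after
g generations is z^g, every node created at generation g sits at depth g,
and 2 z^(g-1) nodes are created in expectation at generation g.  Hence

    E[A_n] = 1 + 2 sum_{g=0}^{n-1} z^g,
    E[C_n] = E[A_n] + 2 sum_{g=1}^{n} g z^(g-1),

implemented as recurrences in :func:`expected_nodes` and
:func:`expected_cumulative` (the recurrence, not any closed form, is the
contract; the test suite cross-checks closed forms and Monte Carlo).  At
large n, A ~ z^n and C ~ n z^n, so d = C/A - 1 ~ n ~ ln A / ln z.

Random-number protocol: one ``numpy`` Generator per replicate, seeded from
``(seed, replicate_index)``, so replicate sets are reproducible and
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree_core import Tree, TreeNode

__all__ = [
    "EvolvabilityConfig",
    "simulate_evolvability",
    "simulate_erm",
    "expected_nodes",
    "expected_cumulative",
    "asymptotic_depth_check",
    "evolvability_subtree_points",
    "evolvability_size_sample",
]


@dataclass(frozen=True)
class EvolvabilityConfig:
    """Parameters of an evolvability-model run.

    Exactly one stopping rule must be set: ``n_generations`` (run exactly
    that many synchronous branching steps) or ``max_nodes`` (run whole
    generations until the node count reaches the cap; the final generation
    completes in full, so realized sizes may overshoot).
    """

    p: float
    n_generations: int | None = None
    max_nodes: int | None = None
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if (self.n_generations is None) == (self.max_nodes is None):
            raise ValueError("exactly one of n_generations / max_nodes must be set")
        if self.n_generations is not None and self.n_generations < 1:
            raise ValueError(f"n_generations must be >= 1, got {self.n_generations}")
        if self.max_nodes is not None and self.max_nodes < 3:
            raise ValueError(f"max_nodes must be >= 3, got {self.max_nodes}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), int(replicate)])


def _evolvability_layers(config: EvolvabilityConfig, rng: np.random.Generator):
    """Run one replicate; return per-generation layers.

    Layer g is a pair ``(parents, capable)``: ``parents[i]`` is the index
    *within layer g-1* of node i's parent, ``capable[i]`` its evolvability
    flag.  Layer 0 is the root.  Because branching is synchronous and only
    capable leaves branch, every node created at generation g has depth g.
    """
    layers: list[tuple[np.ndarray, np.ndarray]] = [
        (np.array([-1]), np.array([True]))
    ]
    total = 1
    g = 0
    while True:
        if config.n_generations is not None:
            if g >= config.n_generations:
                break
        elif total >= config.max_nodes:
            break
        _, capable = layers[-1]
        cap_idx = np.flatnonzero(capable)
        n_events = cap_idx.size
        # both daughters capable with prob p, else one uniform side
        symmetric = rng.random(n_events) < config.p
        side = rng.integers(0, 2, size=n_events)
        child_capable = np.empty((n_events, 2), dtype=bool)
        child_capable[:, 0] = symmetric | (side == 0)
        child_capable[:, 1] = symmetric | (side == 1)
        parents = np.repeat(cap_idx, 2)
        layers.append((parents, child_capable.ravel()))
        total += 2 * n_events
        g += 1
    return layers


def _layers_to_tree(layers) -> Tree:
    root = TreeNode()
    root.capable = bool(layers[0][1][0])
    prev = [root]
    for parents, capable in layers[1:]:
        cur: list[TreeNode] = []
        for j in range(parents.size):
            child = prev[parents[j]].add_child(TreeNode())
            child.capable = bool(capable[j])
            cur.append(child)
        prev = cur
    for i, leaf in enumerate(n for n in root.preorder() if n.is_leaf):
        leaf.label = f"t{i + 1}"
    return Tree(root)


def _layers_to_points(layers) -> tuple[np.ndarray, np.ndarray]:
    """(A, d) of every subtree, vectorized generation-by-generation.

    A_j accumulates child subtree sizes upward; C_j = A_j + sum of child C.
    Valid because parents always live in the previous layer.
    """
    n_layers = len(layers)
    A = [np.ones(parents.size if g else 1, dtype=np.int64)
         for g, (parents, _) in enumerate(layers)]
    for g in range(n_layers - 1, 0, -1):
        np.add.at(A[g - 1], layers[g][0], A[g])
    C = [a.copy() for a in A]
    for g in range(n_layers - 1, 0, -1):
        np.add.at(C[g - 1], layers[g][0], C[g])
    A_all = np.concatenate(A)
    C_all = np.concatenate(C)
    return A_all, C_all / A_all - 1.0


def simulate_evolvability(config: EvolvabilityConfig) -> list[Tree]:
    """Simulate the evolvability model; one strictly binary Tree per
    replicate, every node carrying its ``capable`` flag."""
    trees = []
    for rep in range(config.replicates):
        layers = _evolvability_layers(config, _replicate_rng(config.seed, rep))
        trees.append(_layers_to_tree(layers))
    return trees


def evolvability_subtree_points(
    p: float,
    generations: int,
    replicates: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (A, d) points over all subtrees of ``replicates`` simulated
    trees.  Identical, point for point, to running
    :func:`simulate_evolvability` with the same config and tabulating every
    subtree with :mod:`phylodepth.shape_stats` (asserted in the tests);
    this route skips node objects and is the one the model-fitting loop
    uses."""
    config = EvolvabilityConfig(p=p, n_generations=generations, seed=seed,
                                replicates=replicates)
    As, ds = [], []
    for rep in range(replicates):
        layers = _evolvability_layers(config, _replicate_rng(seed, rep))
        A, d = _layers_to_points(layers)
        As.append(A)
        ds.append(d)
    return np.concatenate(As), np.concatenate(ds)


def evolvability_size_sample(
    p: float,
    generations: int,
    replicates: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo sample of whole-tree summaries, one row per replicate.

    Tracks only per-generation counts (sufficient statistics for A and C,
    since every node created at generation g has depth g):

    * ``A`` — total node count,
    * ``C`` — cumulative branch size ``A + sum_g g * (nodes created at g)``,
    * ``branchings`` / ``asym_events`` — branching events and how many of
      them left one daughter incapable (frequency ~ 1 - p).

    Vectorized across replicates; distributionally identical to the full
    simulator (cross-checked in the tests).
    """
    rng = np.random.default_rng([int(seed) % (2**31)])
    capable = np.ones(replicates, dtype=np.int64)
    A = np.ones(replicates, dtype=np.int64)
    depth_total = np.zeros(replicates, dtype=np.int64)
    branchings = np.zeros(replicates, dtype=np.int64)
    asym = np.zeros(replicates, dtype=np.int64)
    for g in range(1, generations + 1):
        sym = rng.binomial(capable, p)
        branchings += capable
        asym += capable - sym
        new_nodes = 2 * capable
        A += new_nodes
        depth_total += g * new_nodes
        capable = capable + sym  # 2 per symmetric event, 1 per asymmetric
    return pd.DataFrame(
        {"A": A, "C": A + depth_total, "branchings": branchings, "asym_events": asym}
    )


def simulate_erm(
    n_leaves: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Tree:
    """Equal-Rates Markov tree: repeatedly bifurcate a uniformly random
    leaf until the tree has ``n_leaves`` leaves (A = 2 n_leaves - 1)."""
    if n_leaves < 2:
        raise ValueError(f"n_leaves must be >= 2, got {n_leaves}")
    if rng is None:
        rng = np.random.default_rng(seed)
    root = TreeNode()
    leaves = [root]
    draws = rng.random(n_leaves - 1)
    for r in draws:
        j = int(r * len(leaves))
        node = leaves[j]
        left = node.add_child(TreeNode())
        right = node.add_child(TreeNode())
        leaves[j] = left
        leaves.append(right)
    for i, leaf in enumerate(leaves, start=1):
        leaf.label = f"t{i}"
    return Tree(root)


def expected_nodes(n: int, p: float) -> float:
    """E[A_n]: expected node count after n synchronous branching
    generations, by the capable-lineage recurrence (z = 1 + p per step)."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    z = 1.0 + p
    capable = 1.0
    A = 1.0
    for _ in range(n):
        A += 2.0 * capable
        capable *= z
    return A


def expected_cumulative(n: int, p: float) -> float:
    """E[C_n]: expected cumulative branch size after n generations.

    C = sum_j (1 + depth_j) and nodes created at generation g sit at depth
    g, so E[C_n] = E[A_n] + sum_g g E[nodes created at g]."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    z = 1.0 + p
    capable = 1.0
    A = 1.0
    depth_total = 0.0
    for g in range(1, n + 1):
        new_nodes = 2.0 * capable
        A += new_nodes
        depth_total += g * new_nodes
        capable *= z
    return A + depth_total


def asymptotic_depth_check(p: float, n_max: int) -> pd.DataFrame:
    """Expected-depth series d_n = E[C_n]/E[A_n] - 1 against A_n = E[A_n].

    For 0 < p < 1 the ratio d_n / ln A_n converges to 1 / ln(1 + p): the
    model's depth scaling is asymptotically logarithmic (ERM-like) and the
    non-logarithmic regime seen at small sizes is a transient.  Columns:
    n, A, d, ratio.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(
            "asymptotic_depth_check requires 0 < p < 1; at the extremes use "
            "the closed-form reference curves"
        )
    rows = []
    for n in range(1, n_max + 1):
        A = expected_nodes(n, p)
        d = expected_cumulative(n, p) / A - 1.0
        rows.append((n, A, d, d / np.log(A)))
    return pd.DataFrame(rows, columns=["n", "A", "d", "ratio"])
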