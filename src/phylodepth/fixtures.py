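"""Synthetic tree fixtures: worked small examples and seeded random tree
sets, so every analysis is testable offline.

``additional_file1_trees`` reproduces the classic 15-tip worked examples:
a maximally balanced and a fully imbalanced (caterpillar) 15-tip tree,
plus a *synthetic* stand-in for a "real" 15-tip phylogeny — a fixed,
seeded ERM draw, clearly labeled synthetic because no published 15-tip
empirical topology is bundled with this package.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
from scipy import stats as sp_stats

from . import shape_stats
from .reference_topologies import make_caterpillar, make_max_balanced
from .simulators import simulate_erm
from .tree_core import Tree, write_newick

__all__ = [
    "FIXTURE_KINDS",
    "additional_file1_trees",
    "random_binary_trees",
    "sample_powerlaw_sizes",
    "powerlaw_tree_set",
    "make_fixture_set",
]

FIXTURE_KINDS = ("additional_file_1", "random_binary", "powerlaw_sizes")

#: fixed seed of the synthetic pseudo-real 15-tip panel
_PSEUDO_REAL_SEED = 20110606


def additional_file1_trees() -> dict[str, Tree]:
    """The three 15-tip worked-example trees, keyed by name.

    ``pseudo_real_15tip_synthetic`` is a seeded ERM draw standing in for an
    unpublished empirical panel; it is synthetic data.
    """
    return {
        "balanced_15tip": make_max_balanced(15),
        "caterpillar_15tip": make_caterpillar(15),
        "pseudo_real_15tip_synthetic": simulate_erm(15, seed=_PSEUDO_REAL_SEED),
    }


def random_binary_trees(n: int, leaves: int, seed: int = 0) -> list[Tree]:
    """``n`` seeded ERM trees with ``leaves`` tips each."""
    return [
        simulate_erm(leaves, rng=np.random.default_rng([int(seed) % (2**31), i]))
        for i in range(n)
    ]


def sample_powerlaw_sizes(
    n: int,
    gamma: float = 1.6,
    seed: int | np.random.Generator = 0,
    min_size: int = 2,
    max_size: int | None = None,
) -> np.ndarray:
    """Sample ``n`` tip counts from a discrete power law P(T) ~ T^-gamma,
    T >= min_size (rejection from the zeta/Zipf distribution); ``max_size``
    truncates by resampling, for when trees must actually be built."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        [int(seed) % (2**31)]
    )
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = sp_stats.zipf.rvs(gamma, size=2 * (n - filled) + 16, random_state=rng)
        draw = draw[draw >= min_size]
        if max_size is not None:
            draw = draw[draw <= max_size]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def powerlaw_tree_set(
    n: int,
    gamma: float = 1.6,
    seed: int = 0,
    min_size: int = 2,
    max_size: int = 500,
) -> list[Tree]:
    """ERM trees whose tip counts follow a discrete power law (a stand-in
    for a database of protein-family phylogenies with power-law sizes)."""
    rng = np.random.default_rng([int(seed) % (2**31)])
    sizes = sample_powerlaw_sizes(n, gamma, seed=rng, min_size=max(min_size, 2),
                                  max_size=max_size)
    return [simulate_erm(int(T), rng=rng) for T in sizes]


def _write_tree(tree: Tree, name: str, out_dir: str) -> list[str]:
    nwk_path = os.path.join(out_dir, f"{name}.nwk")
    with open(nwk_path, "w") as fh:
        fh.write(write_newick(tree) + "\n")
    tsv_path = os.path.join(out_dir, f"{name}.stats.tsv")
    shape_stats.write_stats_tsv(shape_stats.subtree_stats(tree, tree_id=name), tsv_path)
    return [nwk_path, tsv_path]


def make_fixture_set(kind: str, out_dir: str, seed: int = 0, **params) -> list[str]:
    """Write a fixture tree set to ``out_dir``; returns the written paths.

    kinds: ``additional_file_1`` (the 15-tip worked examples, Newick plus
    per-node (A, d, C, S) annotation TSVs), ``random_binary`` (params: n,
    leaves), ``powerlaw_sizes`` (params: n, gamma, max_size).
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    if kind == "additional_file_1":
        for name, tree in additional_file1_trees().items():
            written += _write_tree(tree, name, out_dir)
    elif kind == "random_binary":
        n = int(params.pop("n", 10))
        leaves = int(params.pop("leaves", 64))
        for i, tree in enumerate(random_binary_trees(n, leaves, seed=seed)):
            written += _write_tree(tree, f"erm_{i:03d}", out_dir)
    elif kind == "powerlaw_sizes":
        n = int(params.pop("n", 100))
        gamma = float(params.pop("gamma", 1.6))
        max_size = int(params.pop("max_size", 500))
        trees = powerlaw_tree_set(n, gamma=gamma, seed=seed, max_size=max_size)
        sizes_path = os.path.join(out_dir, "sizes.tsv")
        with open(sizes_path, "w") as fh:
            fh.write("tree_id\tT\n")
            for i, tree in enumerate(trees):
                name = f"pl_{i:04d}"
                with open(os.path.join(out_dir, f"{name}.nwk"), "w") as tf:
                    tf.write(write_newick(tree) + "\n")
                written.append(os.path.join(out_dir, f"{name}.nwk"))
                fh.write(f"{name}\t{tree.n_leaves}\n")
        written.append(sizes_path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    if params:
        raise ValueError(f"unused fixture parameters: {sorted(params)}")
    return written
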