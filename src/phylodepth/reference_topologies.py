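"""Extreme tree topologies and their closed-form mean-depth curves.

Three shapes bound the mean-depth-vs-size plane for rooted trees of fixed
node count A:

* star (fully polytomic): root with A - 1 leaf children; the unique
  minimizer of mean depth, d = (A - 1)/A -> 1.
* caterpillar (fully imbalanced binary): every internal node has a leaf
  child; the maximizer among binary trees, d = (A^2 - 1)/(4A) ~ A/4.
* fully balanced (complete binary) with k levels, A = 2^(k+1) - 1:
  d = ((k - 1) 2^(k+1) + 2)/(2^(k+1) - 1) ~ ln A / ln 2.

The closed forms were derived under depth(root) = 0 and are validated in
the test suite against the brute-force route (generate the topology, take
:func:`phylodepth.shape_stats.mean_depth`); the generators, not the
formulas, are ground truth.

Derivations: for the caterpillar with L leaves (A = 2L - 1) the internal
nodes sit at depths 0..L-2 and the leaves at 1..L-2 plus two at L-1, so
the depth total is L(L - 1) and d = L(L-1)/(2L-1) = (A^2 - 1)/(4A).  For
the balanced tree, sum_{j=0}^{k} j 2^j = (k - 1) 2^(k+1) + 2.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from .tree_core import Tree, TreeNode

__all__ = [
    "make_star",
    "make_caterpillar",
    "make_balanced",
    "make_max_balanced",
    "closed_form_depth",
    "reference_curve",
    "REFERENCE_KINDS",
]

REFERENCE_KINDS = ("star", "caterpillar", "balanced")


def make_star(n_nodes: int) -> Tree:
    """Fully polytomic tree with ``n_nodes`` nodes: root + (n_nodes - 1) leaves.

    The smallest valid star has 3 nodes (a root with a single child would be
    a unary chain, which this package collapses on ingest).
    """
    if n_nodes < 3:
        raise ValueError(f"star requires n_nodes >= 3, got {n_nodes}")
    root = TreeNode("r")
    for i in range(n_nodes - 1):
        root.add_child(TreeNode(f"t{i + 1}"))
    return Tree(root)


def make_caterpillar(n_leaves: int) -> Tree:
    """Fully imbalanced strictly binary tree with ``n_leaves`` leaves
    (A = 2 * n_leaves - 1 nodes)."""
    if n_leaves < 2:
        raise ValueError(f"caterpillar requires n_leaves >= 2, got {n_leaves}")
    # build bottom-up: deepest cherry first, then hang a leaf at each level
    node = TreeNode()
    node.add_child(TreeNode("t1"))
    node.add_child(TreeNode("t2"))
    for i in range(3, n_leaves + 1):
        new_root = TreeNode()
        new_root.add_child(node)
        new_root.add_child(TreeNode(f"t{i}"))
        node = new_root
    return Tree(node)


def make_balanced(levels: int) -> Tree:
    """Complete (fully balanced) binary tree with ``levels`` bifurcation
    levels below the root: A = 2^(levels+1) - 1 nodes, all leaves at depth
    ``levels``.  ``levels = 0`` gives the lone root."""
    if levels < 0:
        raise ValueError(f"balanced tree requires levels >= 0, got {levels}")
    root = TreeNode("r")
    frontier = [root]
    for _ in range(levels):
        nxt: list[TreeNode] = []
        for node in frontier:
            nxt.append(node.add_child(TreeNode()))
            nxt.append(node.add_child(TreeNode()))
        frontier = nxt
    for i, leaf in enumerate(frontier, start=1):
        leaf.label = f"t{i}"
    return Tree(root)


def make_max_balanced(n_leaves: int) -> Tree:
    """Maximally balanced binary tree with an arbitrary leaf count.

    At every internal node the leaves split ceil/floor; for n_leaves a power
    of two this is the complete binary tree.  Used for fixture trees whose
    tip count (e.g. 15) is not a power of two.
    """
    if n_leaves < 1:
        raise ValueError(f"n_leaves >= 1 required, got {n_leaves}")
    counter = [0]

    root = TreeNode()
    stack = [(root, n_leaves)]
    while stack:
        node, n = stack.pop()
        if n == 1:
            counter[0] += 1
            node.label = f"t{counter[0]}"
            continue
        left = node.add_child(TreeNode())
        right = node.add_child(TreeNode())
        half = (n + 1) // 2
        stack.append((right, n - half))
        stack.append((left, half))
    return Tree(root)


def _balanced_levels(A: int) -> int:
    """levels k such that A = 2^(k+1) - 1, or raise."""
    m = A + 1
    if A >= 1 and (m & (m - 1)) == 0:
        return m.bit_length() - 2
    raise ValueError(
        f"balanced closed form needs A = 2^(k+1) - 1 (1, 3, 7, 15, ...); got {A}"
    )


def closed_form_depth(kind: str, A: int) -> Fraction:
    """Closed-form mean depth d(A) of an extreme topology, exact.

    Admissible sizes: star A >= 3 (any integer); caterpillar odd A >= 3;
    balanced A = 2^(k+1) - 1.  Inadmissible input raises ``ValueError``
    naming the admissible set.
    """
    if kind == "star":
        if A < 3:
            raise ValueError(f"star closed form needs integer A >= 3; got {A}")
        return Fraction(A - 1, A)
    if kind == "caterpillar":
        if A < 3 or A % 2 == 0:
            raise ValueError(f"caterpillar closed form needs odd A >= 3; got {A}")
        return Fraction(A * A - 1, 4 * A)
    if kind == "balanced":
        k = _balanced_levels(A)
        return Fraction((k - 1) * (A + 1) + 2, A)
    raise ValueError(f"unknown kind {kind!r}; expected one of {REFERENCE_KINDS}")


_LEADING_BEHAVIOR = {"star": "~1", "caterpillar": "~A", "balanced": "~ln A"}


def reference_curve(kind: str, max_size: int) -> pd.DataFrame:
    """(A, d) series of the closed-form curve at every admissible A <= max_size.

    ``d`` is emitted as float; the ``leading_behavior`` attribute records
    the large-A scaling tag.
    """
    if kind not in REFERENCE_KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {REFERENCE_KINDS}")
    if kind == "star":
        sizes = range(3, max_size + 1)
    elif kind == "caterpillar":
        sizes = range(3, max_size + 1, 2)
    else:
        sizes = []
        A = 3
        while A <= max_size:
            sizes.append(A)
            A = 2 * A + 1
    rows = [(A, float(closed_form_depth(kind, A))) for A in sizes]
    if not rows:
        raise ValueError(f"no admissible sizes for kind {kind!r} with max_size={max_size}")
    curve = pd.DataFrame(rows, columns=["A", "d"])
    curve.attrs["kind"] = kind
    curve.attrs["leading_behavior"] = _LEADING_BEHAVIOR[kind]
    return curve
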