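"""Per-subtree shape statistics: size A, mean depth d, cumulative branch
size C, and Sackin's index S.

Definitions (depth(root) = 0 throughout):

* ``A``  — number of nodes in the subtree, internal + leaves, root included.
* ``d``  — mean over *all* subtree nodes (not only leaves) of the node's
  topological distance to the subtree root.
* ``C``  — cumulative branch size, the sum over all subtree nodes j of the
  size A_j of the subtree they root.  Equivalently C = sum_j (1 + depth_j),
  so C = A (1 + d): the exact identity d = C/A - 1.
* ``S``  — Sackin's index, the sum of leaf depths.  For strictly binary
  trees C = 2S + 1 (with the lone-root initial condition C = 1, S = 0).

``A``, ``C``, ``S`` are exact integers; ``mean_depth`` returns an exact
``Fraction``.  ``cumulative_branch_size`` accumulates subtree sizes in a
post-order pass while ``mean_depth`` sums depths, so the d = C/A - 1
identity cross-checks two independent computations.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable

import pandas as pd

from .tree_core import Subtree, Tree, TreeNode, _root_of

__all__ = [
    "subtree_size",
    "mean_depth",
    "cumulative_branch_size",
    "sackin_index",
    "subtree_stats",
    "stats_table",
    "write_stats_tsv",
]


def subtree_size(subtree: Tree | Subtree | TreeNode) -> int:
    """A: total node count of the subtree (root included)."""
    return sum(1 for _ in _root_of(subtree).preorder())


def _depth_sums(root: TreeNode) -> tuple[int, int, int]:
    """(node count, sum of node depths, sum of leaf depths).

    Breadth-first by level: whole levels are counted with ``len`` so the
    per-node constant stays small on wide trees.
    """
    n = 0
    depth_sum = 0
    leaf_depth_sum = 0
    d = 0
    level = [root]
    while level:
        k = len(level)
        n += k
        depth_sum += d * k
        nxt: list[TreeNode] = []
        extend = nxt.extend
        n_leaves = 0
        for node in level:
            if node.children:
                extend(node.children)
            else:
                n_leaves += 1
        leaf_depth_sum += d * n_leaves
        level = nxt
        d += 1
    return n, depth_sum, leaf_depth_sum


def mean_depth(subtree: Tree | Subtree | TreeNode) -> Fraction:
    """d: mean topological distance to the subtree root over all nodes."""
    n, depth_sum, _ = _depth_sums(_root_of(subtree))
    return Fraction(depth_sum, n)


def cumulative_branch_size(subtree: Tree | Subtree | TreeNode) -> int:
    """C: sum of A_j over all nodes j of the subtree (post-order pass)."""
    root = _root_of(subtree)
    order = list(root.preorder())
    sizes: dict[TreeNode, int] = {}
    for node in reversed(order):  # children precede parents
        sizes[node] = 1 + sum(sizes[c] for c in node.children)
    return sum(sizes.values())


def sackin_index(subtree: Tree | Subtree | TreeNode) -> int:
    """S: sum of leaf depths; a lone root is a leaf at depth 0, so S = 0."""
    _, _, leaf_depth_sum = _depth_sums(_root_of(subtree))
    return leaf_depth_sum


def subtree_stats(tree: Tree | Subtree | TreeNode, tree_id: str = "tree") -> pd.DataFrame:
    """Statistics for *every* subtree of ``tree`` in a single O(N) pass.

    Columns: tree_id, node_id (preorder rank), A, d, C, S,
    is_binary_subtree.  Leaf rows (A = 1, d = 0) are included; filtering is
    a downstream concern.
    """
    order = list(_root_of(tree).preorder())
    n = len(order)
    index = {node: i for i, node in enumerate(order)}
    parent = [index[node.parent] if node.parent in index else -1 for node in order]
    # root of the view may have a parent outside the view
    parent[0] = -1

    depth = [0] * n
    for i in range(1, n):
        depth[i] = depth[parent[i]] + 1

    A = [1] * n           # subtree node count
    C = [0] * n           # cumulative branch size (filled below)
    LD = [0] * n          # sum of *global* leaf depths within subtree
    LC = [0] * n          # leaf count within subtree
    binary = [True] * n   # all internal nodes in subtree strictly binary
    nchild = [len(node.children) for node in order]
    for i in range(n - 1, -1, -1):
        if nchild[i] == 0:
            LD[i] += depth[i]
            LC[i] += 1
        elif nchild[i] != 2:
            binary[i] = False
        p = parent[i]
        if p >= 0:
            A[p] += A[i]
            LD[p] += LD[i]
            LC[p] += LC[i]
            binary[p] = binary[p] and binary[i]
    # C_j = A_j + sum over children c of C_c, again children-first
    C = list(A)
    for i in range(n - 1, 0, -1):
        C[parent[i]] += C[i]

    S = [LD[i] - LC[i] * depth[i] for i in range(n)]
    d = [C[i] / A[i] - 1.0 for i in range(n)]
    return pd.DataFrame(
        {
            "tree_id": tree_id,
            "node_id": range(n),
            "A": A,
            "d": d,
            "C": C,
            "S": S,
            "is_binary_subtree": binary,
        }
    )


def stats_table(
    tree_set: Iterable[Tree | Subtree | TreeNode] | Iterable[tuple[str, Tree]],
) -> pd.DataFrame:
    """One NodeStat row per node per tree, for a tree set.

    Accepts either bare trees (ids ``tree0 .. treeN``) or ``(id, tree)``
    pairs, e.g. the output of :func:`phylodepth.tree_core.read_tree_set`.
    """
    frames = []
    for i, item in enumerate(tree_set):
        if isinstance(item, tuple):
            tree_id, tree = item
        else:
            tree_id, tree = f"tree{i}", item
        frames.append(subtree_stats(tree, tree_id=tree_id))
    if not frames:
        raise ValueError("empty tree set")
    return pd.concat(frames, ignore_index=True)


def write_stats_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
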