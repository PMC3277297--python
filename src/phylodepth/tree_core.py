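"""Rooted-tree representation, Newick I/O, traversal and subtree enumeration.

Everything downstream works on bare topology: branch lengths present in a
Newick string are parsed and discarded, and unary (single-child) internal
nodes are collapsed on ingest, because every node is interpreted as a
diversification event.

Depth convention
----------------
``depth(root) = 0`` and ``depth(child) = depth(parent) + 1``.  This is the
convention under which a lone root has cumulative branch size C = 1 and
Sackin index S = 0, which in turn makes the exact identities of
:mod:`phylodepth.shape_stats` (d = C/A - 1 and, for binary trees,
C = 2S + 1) hold without offsets.

All traversals are iterative: caterpillar-shaped trees of 10^4 nodes would
blow the recursion limit otherwise.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Iterator, Sequence

import dendropy

logger = logging.getLogger("phylodepth")

__all__ = [
    "TreeNode",
    "Tree",
    "Subtree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_tree_set",
    "node_depths",
    "enumerate_subtrees",
    "polytomy_fraction",
    "topology_equal",
    "topology_signature",
    "node_table",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input; the message names the position."""


class TreeNode:
    """A node of a rooted tree: parent pointer, ordered children, optional label.

    ``capable`` is used by the evolvability simulator to flag whether the
    lineage can still diversify; it is ``None`` for trees from other sources.
    """

    __slots__ = ("parent", "children", "label", "capable")

    def __init__(self, label: str | None = None) -> None:
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.label = label
        self.capable: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["TreeNode"]:
        """Iterative preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            # reversed so that children come out in left-to-right order
            stack.extend(reversed(node.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind}>"


class Subtree:
    """A lightweight view of the subtree rooted at a given node.

    Shares nodes with the parent tree; iteration is preorder.
    """

    __slots__ = ("root",)

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    def __iter__(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    @property
    def size(self) -> int:
        return sum(1 for _ in self)


class Tree:
    """A rooted tree, possibly polytomic.

    Invariants (enforced on ingest, see :func:`parse_newick`): exactly one
    root; leaves have zero children; internal nodes have >= 2 children.
    """

    __slots__ = ("root",)

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    def __iter__(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    @property
    def nodes(self) -> list[TreeNode]:
        return list(self.root.preorder())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self)

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self if n.is_leaf)

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self if not n.is_leaf)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n_nodes={self.n_nodes} n_leaves={self.n_leaves}>"


def _root_of(obj: Tree | Subtree | TreeNode) -> TreeNode:
    """Accept a Tree, a Subtree view, or a bare node as 'a subtree'."""
    if isinstance(obj, TreeNode):
        return obj
    return obj.root


def _collapse_unary(root: TreeNode) -> tuple[TreeNode, int]:
    """Splice out single-child nodes; returns (new root, number collapsed)."""
    collapsed = 0
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        collapsed += 1
    for node in list(root.preorder()):
        # splice repeatedly in case of chains
        i = 0
        while i < len(node.children):
            child = node.children[i]
            while len(child.children) == 1:
                grand = child.children[0]
                grand.parent = node
                node.children[i] = grand
                child = grand
                collapsed += 1
            i += 1
    return root, collapsed


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree (topology only).

    Branch lengths are discarded; polytomies are preserved; unary internal
    nodes are collapsed with a warning.  Malformed input raises
    :class:`NewickParseError` whose message names the offending position.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    mapping: dict[object, TreeNode] = {}
    for dnode in dtree.preorder_node_iter():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label)
        mapping[dnode] = node
        if dnode.parent_node is not None:
            mapping[dnode.parent_node].add_child(node)
    root = mapping[dtree.seed_node]
    root, collapsed = _collapse_unary(root)
    if collapsed:
        logger.warning("collapsed %d unary node(s) on Newick ingest", collapsed)
    return Tree(root)


_NEWICK_UNQUOTED_FORBIDDEN = set(" ()[]':;,")


def _format_label(label: str | None) -> str:
    if label is None:
        return ""
    if any(c in _NEWICK_UNQUOTED_FORBIDDEN for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree | Subtree | TreeNode) -> str:
    """Serialize the topology as a Newick string (no branch lengths).

    Round-trip guarantee: ``parse_newick(write_newick(t))`` is
    topology-identical to ``t``.
    """
    root = _root_of(tree)
    parts: list[str] = []
    # iterative depth-first emit: (node, child cursor)
    stack: list[tuple[TreeNode, int]] = [(root, 0)]
    while stack:
        node, cursor = stack.pop()
        if node.is_leaf:
            parts.append(_format_label(node.label))
            continue
        if cursor == 0:
            parts.append("(")
        if cursor < len(node.children):
            if cursor > 0:
                parts.append(",")
            stack.append((node, cursor + 1))
            stack.append((node.children[cursor], 0))
        else:
            parts.append(")")
            parts.append(_format_label(node.label))
    parts.append(";")
    return "".join(parts)


def read_tree_set(path: str | os.PathLike) -> list[tuple[str, Tree]]:
    """Read a tree set: a Newick file (one tree per line/statement) or a
    directory of ``.nwk``/``.tree``/``.newick`` files.

    Returns ``(tree_id, Tree)`` pairs; ids are ``filename`` or
    ``filename#k`` for multi-tree files.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        out: list[tuple[str, Tree]] = []
        for fname in sorted(os.listdir(path)):
            if os.path.splitext(fname)[1].lower() in (".nwk", ".tree", ".newick"):
                out.extend(
                    (_suffix(fname, i, n), t)
                    for (i, t), n in _read_file(os.path.join(path, fname), fname)
                )
        if not out:
            raise FileNotFoundError(f"no .nwk/.tree/.newick files under {path!r}")
        return out
    fname = os.path.basename(path)
    return [(_suffix(fname, i, n), t) for (i, t), n in _read_file(path, fname)]


def _read_file(path: str, fname: str):
    with open(path) as fh:
        statements = [s.strip() + ";" for s in fh.read().split(";") if s.strip()]
    trees = [parse_newick(s) for s in statements]
    return [((i, t), len(trees)) for i, t in enumerate(trees)]


def _suffix(fname: str, i: int, n: int) -> str:
    stem = os.path.splitext(fname)[0]
    return stem if n == 1 else f"{stem}#{i}"


def node_depths(tree: Tree | Subtree | TreeNode) -> dict[TreeNode, int]:
    """Depth of every node: edge count to the (sub)tree root, root -> 0."""
    root = _root_of(tree)
    depths: dict[TreeNode, int] = {}
    stack: list[tuple[TreeNode, int]] = [(root, 0)]
    while stack:
        node, d = stack.pop()
        depths[node] = d
        for child in node.children:
            stack.append((child, d + 1))
    return depths


def enumerate_subtrees(tree: Tree | Subtree | TreeNode) -> Iterator[Subtree]:
    """Yield one Subtree view per node (whole tree first, leaves included)."""
    for node in _root_of(tree).preorder():
        yield Subtree(node)


def polytomy_fraction(tree_set: Iterable[Tree | Subtree | TreeNode]) -> float:
    """Fraction of internal nodes with more than two children, pooled over
    the set.  Raises ``ValueError`` if the set contains no internal node."""
    n_internal = 0
    n_poly = 0
    for tree in tree_set:
        for node in _root_of(tree).preorder():
            if node.children:
                n_internal += 1
                if len(node.children) > 2:
                    n_poly += 1
    if n_internal == 0:
        raise ValueError("tree set contains no internal node; polytomy fraction undefined")
    return n_poly / n_internal


def topology_signature(tree: Tree | Subtree | TreeNode) -> tuple:
    """Canonical label-free shape signature (children sorted recursively).

    Two (sub)trees have equal signatures iff they are topologically
    identical as unlabeled rooted trees.  The result is a nested tuple as
    deep as the tree; intended for small trees — use
    :func:`topology_equal` for large/deep ones (its flat encoding avoids
    deep tuple comparisons).
    """
    root = _root_of(tree)
    sig: dict[TreeNode, tuple] = {}
    # post-order via reversed preorder: children always before parents
    order = list(root.preorder())
    for node in reversed(order):
        if node.is_leaf:
            sig[node] = ()
        else:
            sig[node] = tuple(sorted(sig[c] for c in node.children))
    return sig[root]


def topology_equal(a: Tree | Subtree | TreeNode, b: Tree | Subtree | TreeNode) -> bool:
    """True iff the two rooted topologies are identical ignoring labels.

    Uses hash-consing over a table shared by the two trees: each distinct
    shape gets an integer id, so equality of arbitrarily deep trees needs
    no nested-structure comparison.
    """
    shape_ids: dict[tuple, int] = {}

    def encode(root: TreeNode) -> int:
        ids: dict[TreeNode, int] = {}
        for node in reversed(list(root.preorder())):
            key = tuple(sorted(ids[c] for c in node.children))
            ids[node] = shape_ids.setdefault(key, len(shape_ids))
        return ids[root]

    return encode(_root_of(a)) == encode(_root_of(b))


def node_table(tree: Tree, tree_id: str = "tree"):
    """Per-node debugging table: tree_id, node_id, parent_id, depth, n_children.

    Node ids are preorder ranks; returns a pandas DataFrame.
    """
    import pandas as pd

    depths = node_depths(tree)
    ids = {node: i for i, node in enumerate(tree.root.preorder())}
    rows = [
        {
            "tree_id": tree_id,
            "node_id": ids[node],
            "parent_id": ids[node.parent] if node.parent is not None else -1,
            "depth": depths[node],
            "n_children": len(node.children),
        }
        for node in ids
    ]
    return pd.DataFrame(rows)
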