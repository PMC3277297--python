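import numpy as np
import pytest

from phylodepth import Tree, parse_newick, simulate_erm


@pytest.fixture
def cherry() -> Tree:
    return parse_newick("(A,B);")


@pytest.fixture
def caterpillar3() -> Tree:
    """3-leaf caterpillar: 5 nodes."""
    return parse_newick("((A,B),C);")


@pytest.fixture
def star3() -> Tree:
    return parse_newick("(A,B,C);")


def random_polytomic_tree(seed: int, n_leaves: int = 30, contract_prob: float = 0.3) -> Tree:
    """A random tree with polytomies: an ERM draw with random internal
    edges contracted (child's children lifted to the parent)."""
    rng = np.random.default_rng(seed)
    tree = simulate_erm(n_leaves, rng=rng)
    for node in list(tree.root.preorder()):
        if node is tree.root or node.is_leaf:
            continue
        if rng.random() < contract_prob:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for child in node.children:
                child.parent = parent
            node.parent = None
    return tree
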