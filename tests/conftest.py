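import numpy as np
import pytest

from phyloconflict.tree_core import (RootedTree, SubstitutionModel, TreeNode,
                                     TopologyConstraint,
                                     enumerate_rooted_topologies,
                                     parse_newick)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def jc():
    return SubstitutionModel.jc69()


@pytest.fixture(scope="session")
def four_taxon_topologies():
    return enumerate_rooted_topologies(list("ABCD"))


@pytest.fixture(scope="session")
def study_candidates():
    """The 15 ingroup topologies with the outgroup fixed at the root."""
    constraint = TopologyConstraint(fixed_outgroup="ela")
    return enumerate_rooted_topologies(
        ["att", "dai", "lgk", "mus", "ela"], constraint)


def balanced_tree(depth: int, branch: float = 1.0) -> RootedTree:
    """Fully balanced binary tree with 2**depth tips, unit branches."""

    def rec(d, prefix):
        node = TreeNode(length=branch)
        if d == 0:
            node.name = prefix
            return node
        node.add_child(rec(d - 1, prefix + "0"))
        node.add_child(rec(d - 1, prefix + "1"))
        return node

    root = rec(depth, "t")
    root.length = None
    return RootedTree(root)


def random_tree(labels, rng, min_len=0.01, max_len=0.5) -> RootedTree:
    """Random rooted binary tree by stepwise leaf insertion."""
    labels = list(labels)
    assert len(labels) >= 2
    tree = parse_newick(f"({labels[0]}:1,{labels[1]}:1);")
    for label in labels[2:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        edge = edges[rng.integers(0, len(edges))]
        parent = edge.parent
        mid = TreeNode(length=edge.length / 2 if edge.length else None)
        edge.length = edge.length / 2 if edge.length else None
        parent.children[parent.children.index(edge)] = mid
        mid.parent = parent
        mid.add_child(edge)
        mid.add_child(TreeNode(label, 1.0))
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(min_len, max_len))
    return tree
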