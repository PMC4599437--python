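import itertools

import dendropy
import numpy as np
import pytest

import bgcphylo as bp

STRAINS = ["H_cretacea", "H_mongoliensis", "H_yilanensis", "H_daliensis",
           "H_sakaeratensis"]


@pytest.fixture(scope="session")
def inventories():
    return bp.load_herbidospora_inventories()


@pytest.fixture(scope="session")
def by_strain(inventories):
    return {inv.strain_id: inv for inv in inventories}


@pytest.fixture(scope="session")
def species_tree():
    return bp.load_tree(bp.load_herbidospora_tree_path())


@pytest.fixture(scope="session")
def ingroup_tree(species_tree):
    return bp.root_with_outgroup(species_tree, "Acrocarpospora_corrugata",
                                 prune_outgroup=True)


# ---------------------------------------------------------------------------
# Tree helpers shared by phylogenetics and gain/loss tests


def random_binary_tree(rng: np.random.Generator, taxa: list[str],
                       bl_low: float = 0.05, bl_high: float = 0.5
                       ) -> dendropy.Tree:
    """Random rooted binary tree with uniform branch lengths."""

    nodes = []
    for name in taxa:
        n = dendropy.Node()
        n._label_for_test = name
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(bl_low, bl_high))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree()
    tree.seed_node = nodes[0]
    tns = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.new_taxon(leaf._label_for_test)
    tree.is_rooted = True
    return tree


def additive_matrix(tree: dendropy.Tree) -> bp.DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(by_label[a],
                                                       by_label[taxa[j]])
    return bp.DistanceMatrix(tuple(taxa), d)


def enumerate_rooted_trees(leaves: list[str]):
    """All rooted binary tree shapes over labeled leaves, as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for shape in enumerate_rooted_trees(rest):
        yield from _insert_leaf(shape, first)


def _insert_leaf(shape, leaf):
    # attach on the root stem
    yield (leaf, shape)
    if isinstance(shape, tuple):
        left, right = shape
        for sub in _insert_leaf(left, leaf):
            yield (sub, right)
        for sub in _insert_leaf(right, leaf):
            yield (left, sub)


def tuple_tree_to_dendropy(shape) -> dendropy.Tree:
    def newick(s):
        if isinstance(s, tuple):
            return f"({newick(s[0])},{newick(s[1])})"
        return s

    tree = dendropy.Tree.get(data=newick(shape) + ";", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def tuple_tree_leaves(shape) -> set[str]:
    if isinstance(shape, tuple):
        return tuple_tree_leaves(shape[0]) | tuple_tree_leaves(shape[1])
    return {shape}


def dollo_oracle(shape, present: set[str]) -> int:
    """Minimum event count (1 gain + losses) by brute force over every gain
    placement with implied losses."""

    def subtrees(s):
        yield s
        if isinstance(s, tuple):
            yield from subtrees(s[0])
            yield from subtrees(s[1])

    def losses_needed(s) -> int:
        leaves = tuple_tree_leaves(s)
        if leaves.isdisjoint(present):
            return 1  # this whole subtree is lost: one loss event
        if not isinstance(s, tuple):
            return 0
        return losses_needed(s[0]) + losses_needed(s[1])

    best = None
    for gain in subtrees(shape):
        leaves = tuple_tree_leaves(gain)
        if not present <= leaves:
            continue
        events = 1 + (losses_needed(gain) if isinstance(gain, tuple) else 0)
        best = events if best is None else min(best, events)
    return best
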