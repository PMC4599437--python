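"""Distances, neighbor joining, bootstrap, rooting and RF comparison."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from bgcphylo.phylo import (DistanceMatrix, bootstrap, msa_distances,
                            nj_tree, rf_distance, root_with_outgroup)
from bgcphylo.simulate import simulate_alignment
from tests.conftest import additive_matrix, random_binary_tree


def tree_from_newick(nwk, rooted=False):
    t = dendropy.Tree.get(data=nwk, schema="newick",
                          preserve_underscores=True)
    t.is_rooted = rooted
    return t


class TestDistances:
    def test_identical_sequences(self):
        dm = msa_distances({"a": "ACGTACGT", "b": "ACGTACGT"}, model="p")
        assert dm.get("a", "b") == 0.0

    def test_quarter_mismatch(self):
        dm = msa_distances({"a": "AAAA", "b": "AAAT"}, model="p")
        assert dm.get("a", "b") == pytest.approx(0.25)

    def test_jc69_closed_form(self):
        dm = msa_distances({"a": "AAAA", "b": "AAAT"}, model="JC69")
        assert dm.get("a", "b") == pytest.approx(-0.75 * math.log(2 / 3))
        assert dm.get("a", "b") == pytest.approx(0.3041, abs=1e-4)

    def test_pairwise_deletion(self):
        dm = msa_distances({"a": "AC-TA", "b": "ANGTT"}, model="p")
        # comparable sites: positions 1, 4, 5 -> one mismatch of three
        assert dm.get("a", "b") == pytest.approx(1 / 3)

    def test_no_comparable_sites_error(self):
        with pytest.raises(ValueError, match="a and b"):
            msa_distances({"a": "--AA", "b": "GG--"})

    def test_saturation_error(self):
        with pytest.raises(ValueError, match="saturated"):
            msa_distances({"a": "ACGTACGT", "b": "CAGAGTAC"}, model="JC69")


def all_quartet_and_quintet_topologies(taxa):
    """All unrooted binary topologies over taxa (3 for 4 taxa, 15 for 5)."""
    if len(taxa) == 4:
        a, b, c, d = taxa
        return [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    tops = []
    for quartet_top in all_quartet_and_quintet_topologies(taxa[:-1]):
        # graft the fifth leaf on each of the 5 edges of the quartet tree
        (p, q), (r, s) = quartet_top
        e = taxa[-1]
        tops.extend([
            (((p, e), q), (r, s)), (((q, e), p), (r, s)),
            ((p, q), ((r, e), s)), ((p, q), ((s, e), r)),
            ((p, q), (r, s), e),  # central edge
        ])
    return tops


def ls_fit_error(top, dm: DistanceMatrix) -> float:
    """Ordinary least-squares branch-length fit of one topology; returns
    the residual sum of squares (the oracle for NJ on additive data)."""
    nwk = _to_newick(top)
    tree = tree_from_newick(nwk)
    tree.encode_bipartitions()
    taxa = sorted(dm.taxa)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    A = np.zeros((len(pairs), len(edges)))
    leaf_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for row, (i, j) in enumerate(pairs):
        path = _edge_path(leaf_of[taxa[i]], leaf_of[taxa[j]])
        for k, e in enumerate(edges):
            if e in path:
                A[row, k] = 1.0
    y = np.array([dm.get(taxa[i], taxa[j]) for i, j in pairs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


def _edge_path(leaf_a, leaf_b):
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    path = set()
    node = leaf_b
    while node not in anc_a:
        path.add(node.edge)
        node = node.parent_node
    mrca = node
    node = leaf_a
    while node is not mrca:
        path.add(node.edge)
        node = node.parent_node
    return path


def _to_newick(top) -> str:
    def render(t):
        if isinstance(t, tuple):
            return "(" + ",".join(render(x) for x in t) + ")"
        return t

    return render(top) + ";"


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_recovers_known_five_taxon_tree(self):
        rng = np.random.default_rng(11)
        true = random_binary_tree(rng, list("abcde"))
        dm = additive_matrix(true)
        est = nj_tree(dm)
        assert rf_distance(est, true) == 0
        # branch lengths are recovered exactly on additive input
        est_dm = additive_matrix(est)
        assert np.allclose(est_dm.values, dm.values, atol=1e-9)

    def test_against_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        taxa = list("abcde")
        true = random_binary_tree(rng, taxa)
        dm = additive_matrix(true)
        tops = all_quartet_and_quintet_topologies(sorted(taxa))
        errors = [ls_fit_error(t, dm) for t in tops]
        best = tree_from_newick(_to_newick(tops[int(np.argmin(errors))]))
        assert rf_distance(nj_tree(dm), best) == 0

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(3)
        true = random_binary_tree(rng, list("abcdef"))
        dm = additive_matrix(true)
        perm = rng.permutation(len(dm.taxa))
        dm2 = DistanceMatrix(tuple(np.array(dm.taxa)[perm]),
                             dm.values[np.ix_(perm, perm)])
        assert rf_distance(nj_tree(dm), nj_tree(dm2)) == 0

    def test_consistency_on_random_trees(self):
        """Additive matrices from 100 random 5-8 taxon trees are inverted
        exactly."""
        rng = np.random.default_rng(2024)
        for i in range(100):
            n = int(rng.integers(5, 9))
            taxa = [f"t{k}" for k in range(n)]
            true = random_binary_tree(rng, taxa)
            assert rf_distance(nj_tree(additive_matrix(true)), true) == 0

    def test_matches_independent_implementation(self):
        import skbio

        rng = np.random.default_rng(17)
        for _ in range(5):
            true = random_binary_tree(rng, [f"t{k}" for k in range(7)])
            dm = additive_matrix(true)
            ours = nj_tree(dm)
            theirs_nwk = str(
                skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.taxa),
                              result_constructor=lambda x: x))
            theirs = tree_from_newick(theirs_nwk)
            assert rf_distance(ours, theirs) == 0


@pytest.fixture(scope="module")
def tree_and_alignment():
    rng = np.random.default_rng(8)
    tree = random_binary_tree(rng, list("abcde"), 0.05, 0.2)
    return tree, simulate_alignment(tree, 5000, seed=9)


class TestBootstrap:

    def test_strong_signal_high_support(self, tree_and_alignment):
        tree, aln = tree_and_alignment
        full = bootstrap(aln, replicates=100, seed=1)
        supports = [n.support for n in full.preorder_node_iter()
                    if getattr(n, "support", None) is not None]
        assert supports and min(supports) >= 95

    def test_single_replicate_supports_binary(self, tree_and_alignment):
        _, aln = tree_and_alignment
        full = bootstrap(aln, replicates=1, seed=4)
        supports = {n.support for n in full.preorder_node_iter()
                    if getattr(n, "support", None) is not None}
        assert supports <= {0.0, 100.0}

    def test_seed_determinism(self, tree_and_alignment):
        _, aln = tree_and_alignment
        def run():
            full = bootstrap(aln, replicates=20, seed=123)
            return [n.support for n in full.preorder_node_iter()
                    if getattr(n, "support", None) is not None]
        assert run() == run()

    def test_supports_bounded(self, tree_and_alignment):
        _, aln = tree_and_alignment
        full = bootstrap(aln, replicates=25, seed=5)
        for n in full.preorder_node_iter():
            s = getattr(n, "support", None)
            if s is not None:
                assert 0.0 <= s <= 100.0


class TestRooting:
    def test_outgroup_rooting_and_pruning(self):
        t = tree_from_newick("((a:1,b:1):1,(c:1,out:2):1);")
        rooted = root_with_outgroup(t, "out")
        assert rooted.is_rooted
        kids = rooted.seed_node.child_nodes()
        labels = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"out"} in labels
        pruned = root_with_outgroup(t, "out", prune_outgroup=True)
        assert {lf.taxon.label for lf in pruned.leaf_node_iter()} == \
            {"a", "b", "c"}

    def test_root_then_unroot_is_identity(self):
        t = tree_from_newick("((a:1,b:1):1,(c:1,(d:1,out:2):1):1);")
        rooted = root_with_outgroup(t, "out")
        assert rf_distance(rooted, t) == 0

    def test_missing_outgroup_errors(self):
        t = tree_from_newick("((a:1,b:1):1,(c:1,d:2):1);")
        with pytest.raises(ValueError, match="nope"):
            root_with_outgroup(t, "nope")


class TestRobinsonFoulds:
    def test_self_distance_zero(self):
        t = tree_from_newick("((a,b),(c,d),e);")
        assert rf_distance(t, t) == 0

    def test_resolved_quartet_alternatives(self):
        a = tree_from_newick("((a,b),(c,d));")
        b = tree_from_newick("((a,c),(b,d));")
        assert rf_distance(a, b) == 2

    def test_star_versus_resolved(self):
        star = tree_from_newick("(a,b,c,d,e);")
        resolved = tree_from_newick("((a,b),(c,d),e);")
        assert rf_distance(star, resolved) == 2

    def test_leaf_set_mismatch(self):
        a = tree_from_newick("((a,b),(c,d));")
        b = tree_from_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(a, b)

    def test_metric_properties_spot_check(self):
        rng = np.random.default_rng(21)
        taxa = [f"t{k}" for k in range(6)]
        trees = [random_binary_tree(rng, taxa) for _ in range(4)]
        for x in trees:
            assert rf_distance(x, x) == 0
        for x, y in itertools.combinations(trees, 2):
            assert rf_distance(x, y) == rf_distance(y, x) >= 0
        for x, y, z in itertools.permutations(trees, 3):
            assert rf_distance(x, z) <= rf_distance(x, y) + rf_distance(y, z)
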