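"""Distance-based phylogenetics: pairwise distances from an alignment,
neighbor joining, bootstrap support, outgroup rooting and Robinson-Foulds
topology comparison.

Trees are dendropy objects throughout.  Neighbor joining is implemented
here rather than delegated so that tie-breaking (lexicographic over taxon
pairs) and the treatment of negative branch lengths (clamped to zero with
a warning) are deterministic and documented; exactness on additive
matrices is covered by tests, including a cross-check against an
independent implementation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "DistanceMatrix",
    "msa_distances",
    "nj_tree",
    "bootstrap",
    "root_with_outgroup",
    "rf_distance",
    "load_tree",
    "tree_to_newick",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def _seq_items(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, MultipleSeqAlignment):
        return [(rec.id, str(rec.seq).upper()) for rec in alignment]
    if isinstance(alignment, dict):
        return [(k, str(v).upper()) for k, v in alignment.items()]
    return [(rec.id, str(rec.seq).upper()) for rec in alignment]


def msa_distances(alignment, model: str = "JC69") -> DistanceMatrix:
    """Pairwise distances under p-distance or the one-parameter (JC69)
    correction ``-(3/4) ln(1 - 4p/3)``, with pairwise deletion of sites
    where either sequence is a gap or ambiguity."""
    items = _seq_items(alignment)
    if len({len(s) for _, s in items}) > 1:
        raise ValueError("aligned sequences must have equal length")
    names = [n for n, _ in items]
    arrays = [np.frombuffer(s.encode(), dtype="S1") for _, s in items]
    valid = [np.isin(a, [c.encode() for c in _VALID]) for a in arrays]
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            p = float((arrays[i][both] != arrays[j][both]).sum()) / compared
            if model.lower() in ("p", "p-distance"):
                dist = p
            elif model.lower() == "jc69":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {names[i]} and "
                        f"{names[j]} is saturated under JC69"
                    )
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(names), d)


def nj_tree(dm: DistanceMatrix,
            taxon_namespace: dendropy.TaxonNamespace | None = None
            ) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.  Returns an unrooted dendropy tree;
    exact on additive matrices.  Q-matrix ties are broken by the
    lexicographically smallest (label, label) pair; negative branch
    lengths are clamped to zero with a warning."""
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(sorted(dm.taxa))
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: dict[str, dendropy.Node] = {}
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(name) or tns.new_taxon(name)
        nodes[name] = node

    labels = list(dm.taxa)
    d = {
        (a, b): dm.get(a, b) for a in labels for b in labels if a != b
    }

    def clamp(x: float, where: str) -> float:
        if x < 0:
            warnings.warn(f"negative branch length {x:.4g} at {where} "
                          "clamped to 0")
            return 0.0
        return x

    step = 0
    while len(labels) > 3:
        m = len(labels)
        r = {a: sum(d[(a, b)] for b in labels if b != a) for a in labels}
        best = None
        for a, b in ((x, y) for i, x in enumerate(labels)
                     for y in labels[i + 1:]):
            pair = tuple(sorted((a, b)))
            q = (m - 2) * d[(a, b)] - r[a] - r[b]
            if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair < best[1]):
                best = (q, pair, (a, b))
        _, _, (a, b) = best
        dab = d[(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        step += 1
        new_label = f"__nj{step}({min(a, b)})"
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = clamp(la, f"{a}")
        nodes[b].edge.length = clamp(lb, f"{b}")
        nodes[new_label] = parent
        for c in labels:
            if c in (a, b):
                continue
            d[(new_label, c)] = d[(c, new_label)] = 0.5 * (
                d[(a, c)] + d[(b, c)] - dab
            )
        labels = [c for c in labels if c not in (a, b)] + [new_label]
        for c in (a, b):
            for e in list(d):
                if c in e:
                    del d[e]

    a, b, c = labels
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    center = tree.seed_node
    for label, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[label])
        nodes[label].edge.length = clamp(length, label)
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _resample_columns(items: list[tuple[str, str]],
                      rng: np.random.Generator) -> dict[str, str]:
    length = len(items[0][1])
    idx = rng.integers(0, length, size=length)
    return {name: "".join(seq[i] for i in idx) for name, seq in items}


def bootstrap(alignment, replicates: int, seed: int,
              model: str = "JC69", builder=nj_tree) -> dendropy.Tree:
    """Column-resampling bootstrap.  Internal edges of the full-data tree
    are annotated (``node.support``, also set as node label) with the
    percentage of replicates reproducing their bipartition."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    items = _seq_items(alignment)
    rng = np.random.default_rng(seed)
    full = builder(msa_distances(alignment, model))
    tns = full.taxon_namespace
    full.encode_bipartitions()

    counts: dict = {}
    for _ in range(replicates):
        rep = builder(msa_distances(_resample_columns(items, rng), model),
                      taxon_namespace=tns)
        rep.encode_bipartitions()
        for bp in rep.bipartition_encoding:
            counts[bp.split_bitmask] = counts.get(bp.split_bitmask, 0) + 1

    leaf_count = len(tns)
    for node in full.preorder_node_iter():
        if node.is_leaf() or node is full.seed_node:
            continue
        bitmask = node.edge.bipartition.split_bitmask
        size = bin(bitmask).count("1")
        if size <= 1 or size >= leaf_count - 1:
            continue  # trivial bipartition
        pct = 100.0 * counts.get(bitmask, 0) / replicates
        node.support = pct
        node.label = str(int(round(pct)))
    return full


def root_with_outgroup(tree: dendropy.Tree, taxon: str,
                       prune_outgroup: bool = False) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's pendant edge; optionally
    prune the outgroup, leaving the rooted ingroup tree."""
    rooted = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon and lf.taxon.label == taxon:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup taxon {taxon!r} not in tree")
    length = leaf.edge.length or 0.0
    rooted.reroot_at_edge(leaf.edge, length1=length / 2.0,
                          length2=length / 2.0,
                          update_bipartitions=False)
    rooted.is_rooted = True
    if prune_outgroup:
        rooted.prune_taxa([leaf.taxon], suppress_unifurcations=True)
        if len(rooted.seed_node.child_nodes()) == 1:
            child = rooted.seed_node.child_nodes()[0]
            rooted.seed_node = child
            child.parent_node = None
    return rooted


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric difference of
    non-trivial bipartitions)."""
    leaves_a = {lf.taxon.label for lf in a.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in b.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError(
            f"leaf sets differ: {sorted(leaves_a ^ leaves_b)}"
        )
    tns = dendropy.TaxonNamespace(sorted(leaves_a))
    ta = dendropy.Tree.get(data=a.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=b.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns)
    ta.is_rooted = tb.is_rooted = False
    ta.update_bipartitions()
    tb.update_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))


def load_tree(path, rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = rooted
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)
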