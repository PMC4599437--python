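"""Dollo-parsimony gain/loss mapping of pathway presence/absence.

Each pathway (ortholog group) is assumed to have been acquired exactly
once; absences below the acquisition are explained by losses.  Under this
model the most parsimonious history is unique: the gain sits on the branch
above the MRCA of all strains carrying the pathway, and the losses are the
stem branches of the maximal all-absent subtrees below it.  Events are
attributed to the branch *above* a node, i.e. a loss "just before
evolution to X" sits on the pendant branch of X.

A Fitch-style unordered-parsimony mode is not provided here; the single
gain assumption is part of the model (horizontal acquisition of a whole
cluster twice independently in one genus is not considered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = ["EventMap", "dollo_map", "summarize_events", "branch_id"]


def branch_id(node: dendropy.Node, tree: dendropy.Tree) -> str:
    """Stable identifier of the branch above ``node``: the leaf label for
    pendant branches, "root" for the stem above the root, otherwise the
    sorted, comma-joined labels of the subtended leaves."""
    if node is tree.seed_node:
        return "root"
    if node.is_leaf():
        return node.taxon.label
    return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


@dataclass
class EventMap:
    group_id: str
    gain_branch: str
    loss_branches: tuple[str, ...]
    ancestral_states: dict[str, str]
    leaf_set: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_events(self) -> int:
        return 1 + len(self.loss_branches)


def dollo_map(tree: dendropy.Tree, presence: dict[str, int],
              group_id: str = "") -> EventMap:
    """Map one pathway's presence row onto a rooted tree under Dollo
    parsimony."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = set(leaves) - set(presence)
    if missing:
        raise ValueError(f"presence row lacks states for {sorted(missing)}")
    present = {name for name in leaves if presence[name]}
    if not present:
        raise ValueError("all-absent presence row: no gain can be placed")

    if len(present) == 1:
        gain_node = leaves[next(iter(present))]
    else:
        gain_node = tree.mrca(taxon_labels=sorted(present))

    losses: list[dendropy.Node] = []

    def collect_losses(node: dendropy.Node) -> None:
        leaf_labels = {lf.taxon.label for lf in node.leaf_iter()} \
            if not node.is_leaf() else {node.taxon.label}
        if leaf_labels.isdisjoint(present):
            losses.append(node)
            return
        for child in node.child_nodes():
            collect_losses(child)

    for child in gain_node.child_nodes():
        collect_losses(child)

    lost_clades = [
        {lf.taxon.label for lf in n.leaf_iter()} if not n.is_leaf()
        else {n.taxon.label}
        for n in losses
    ]

    states: dict[str, str] = {}
    gain_clade = ({lf.taxon.label for lf in gain_node.leaf_iter()}
                  if not gain_node.is_leaf() else {gain_node.taxon.label})
    for node in tree.preorder_node_iter():
        nid = branch_id(node, tree)
        node_leaves = ({lf.taxon.label for lf in node.leaf_iter()}
                       if not node.is_leaf() else {node.taxon.label})
        inside_gain = node_leaves <= gain_clade
        inside_loss = any(node_leaves <= lost for lost in lost_clades)
        states[nid] = "present" if inside_gain and not inside_loss else "absent"

    return EventMap(
        group_id=group_id,
        gain_branch=branch_id(gain_node, tree),
        loss_branches=tuple(sorted(branch_id(n, tree) for n in losses)),
        ancestral_states=states,
        leaf_set=frozenset(leaves),
    )


def summarize_events(maps: list[EventMap], tree: dendropy.Tree
                     ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-branch gain/loss tallies and a per-group history class.

    Classes: ``ancestral`` (gained on the root stem, never lost),
    ``recent`` (gained on a pendant branch), ``gain-then-loss`` (any loss),
    and ``intermediate`` (gained on an internal branch, never lost).
    """
    tree_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    branch_ids = [branch_id(n, tree) for n in tree.preorder_node_iter()]
    leaf_ids = tree_leaves

    gains = {b: 0 for b in branch_ids}
    losses = {b: 0 for b in branch_ids}
    classes: dict[str, str] = {}
    for em in maps:
        if em.leaf_set != tree_leaves:
            raise ValueError(
                f"event map {em.group_id} was computed on a different tree"
            )
        gains[em.gain_branch] += 1
        for b in em.loss_branches:
            losses[b] += 1
        if em.loss_branches:
            classes[em.group_id] = "gain-then-loss"
        elif em.gain_branch == "root":
            classes[em.group_id] = "ancestral"
        elif em.gain_branch in leaf_ids:
            classes[em.group_id] = "recent"
        else:
            classes[em.group_id] = "intermediate"

    table = pd.DataFrame(
        {"gains": pd.Series(gains), "losses": pd.Series(losses)}
    )
    table.index.name = "branch"
    return table, classes
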