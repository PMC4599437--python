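"""Reconstruct pathway gain/loss histories on the species tree.

A neighbor-joining 16S tree (here: the packaged reconstructed topology,
rooted on the outgroup) carries each pathway's presence/absence row;
under Dollo parsimony every pathway is acquired once and absences below
the acquisition are losses.
"""

from collections import Counter

import bgcphylo as bp

inventories = bp.load_herbidospora_inventories()
tree = bp.load_tree(bp.load_herbidospora_tree_path())

report = bp.analyze_inventories(inventories, tree=tree,
                                outgroup="Acrocarpospora_corrugata")

print("History classes:", dict(Counter(report.event_classes.values())))
print("\nGain/loss events of the shared pathways:")
for em in report.events:
    if report.event_classes[em.group_id] in ("gain-then-loss", "intermediate"):
        losses = ", ".join(em.loss_branches) or "none"
        print(f"  {em.group_id:8} gained above [{em.gain_branch}], "
              f"lost on [{losses}]")

# e.g. pks-2 was acquired at the genus root and lost on the pendant branch
# of H. cretacea; nrps-8 was acquired on the stem of the
# yilanensis/daliensis/sakaeratensis clade and never lost.
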