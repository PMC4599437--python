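"""Validate the pipeline end to end on synthetic data with known truth.

The generators plant ortholog groups, module plans, sequences and
gain/loss events; the pipeline must recover them.
"""

import dendropy

import bgcphylo as bp
from bgcphylo.assembly import count_modules, segment_modules
from bgcphylo.gainloss import dollo_map
from bgcphylo.orthologs import group_orthologs
from bgcphylo.phylo import msa_distances, nj_tree, rf_distance

# 1. inventories: module plans and planted ortholog groups
inventories, truth = bp.simulate_inventory(seed=7)
ok = sum(
    count_modules(segment_modules(c))["total"]
    == truth.planned_modules[(inv.strain_id, c.cluster_id)]["total"]
    for inv in inventories for c in inv.clusters
)
total = sum(len(inv.clusters) for inv in inventories)
print(f"module plans recovered: {ok}/{total}")
groups = group_orthologs(inventories)
print(f"ortholog groups: {len(groups)} found, "
      f"{len(set(truth.true_groups.values()))} planted")

# 2. sequence evolution: neighbor joining inverts the generating tree
tree = dendropy.Tree.get(
    data="((a:0.05,b:0.07):0.04,(c:0.06,(d:0.05,e:0.08):0.03):0.05);",
    schema="newick")
tree.is_rooted = True
alignment = bp.simulate_alignment(tree, length=5000, seed=7)
estimate = nj_tree(msa_distances(alignment))
print(f"tree recovery: RF distance to truth = {rf_distance(estimate, tree)}")

# 3. presence evolution: Dollo maps never exceed the true event count
matrix, events = bp.simulate_presence_evolution(tree, n_groups=200,
                                                loss_prob_per_branch=0.15,
                                                seed=7)
violations = sum(
    dollo_map(tree, matrix[em.group_id].to_dict()).n_events > em.n_events
    for em in events
)
print(f"parsimony bound violations: {violations}/200 (expect 0)")
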