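"""Group orthologous pathways across the five strains and tally their
phylogenetic distribution.

Clusters from different strains are the same pathway when at least one
gene pair shares its closest BLASTP homolog and their domain organizations
are (almost) identical; the published row alignment breaks the one tie the
table content cannot.
"""

import bgcphylo as bp
from bgcphylo.orthologs import (classify_sharing, group_orthologs,
                                presence_matrix)

inventories = bp.load_herbidospora_inventories()
strains = [inv.strain_id for inv in inventories]

groups = group_orthologs(inventories, threshold=0.8, row_labels="cluster_id")
sharing = classify_sharing(groups, len(strains), strains)

print(f"{len(groups)} pathways identified across {len(strains)} strains")
print(f"  conserved in all strains : {sharing['universal']}")
print(f"  shared by 2-4 strains    : {sharing['partial']}")
print(f"  strain-specific          : {sharing['specific']}")
print("  per-strain specific      :",
      {s: sharing["per_strain_specific"][s] for s in strains})

matrix = presence_matrix(groups, strains)
print("\nPresence/absence of the shared (2-4 strain) pathways:")
partial_cols = [g.group_id for g in groups if 1 < g.n_members < len(strains)]
print(matrix[partial_cols].to_string())
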