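"""Parse the packaged five-strain inventory and segment two extremes of
assembly-line size into modules.

The domain notation encodes each megasynthase ORF; the segmenter turns the
ordered, concatenated domain stream of a cluster into modules, each the
unit of one chain-elongation cycle.
"""

import bgcphylo as bp
from bgcphylo.assembly import count_modules, segment_modules

inventories = bp.load_herbidospora_inventories()
by_strain = {inv.strain_id: inv for inv in inventories}

for inv in inventories:
    print(f"{inv.strain_id}: {len(inv.clusters)} modular NRPS/PKS clusters")

for strain, cid in [("H_cretacea", "pks-6"), ("H_cretacea", "nrps-5")]:
    assembled = segment_modules(by_strain[strain].cluster(cid))
    counts = count_modules(assembled)
    print(f"\n{strain} / {cid}: {counts['total']} modules "
          f"({counts['pks']} PKS, {counts['nrps']} NRPS) across "
          f"{len(assembled.ordered_genes)} genes")
    for m in assembled.counted_modules[:4]:
        print(f"  module {m.index:>2} [{m.role:>9}] "
              f"{'/'.join(m.domain_kinds)}  substrate={m.substrate}")

# pks-6's 35 modules make it the largest modular type-I PKS assembly line
# in the inventory; nrps-5's two modules predict a simple dipeptide.
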