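"""Predict product backbones by the assembly-line rule.

Each module contributes one unit to the product, in order: an amino acid
for NRPS modules, a two-carbon ketide unit for PKS modules.  The ketide
unit's oxidation state follows the module's KR/DH/ER complement.
"""

import bgcphylo as bp
from bgcphylo.assembly import segment_modules
from bgcphylo.backbone import (backbone_to_linear_notation, predict_backbone,
                               product_string, summarize_chemistry)

by_strain = {inv.strain_id: inv for inv in bp.load_herbidospora_inventories()}

print("Peptide products of the conserved NRPS pathways:")
for cid in ["nrps-1", "nrps-2", "nrps-3", "nrps-4", "nrps-5", "nrps-6"]:
    bb = predict_backbone(segment_modules(by_strain["H_cretacea"].cluster(cid)))
    print(f"  {cid:8} {product_string(bb)}")

print("\nPolyketide chemistry of a shared heptaketide pathway (pks-2):")
bb = predict_backbone(segment_modules(by_strain["H_mongoliensis"].cluster("pks-2")))
chem = summarize_chemistry(bb)
print(f"  chain carbons: {chem['chain_carbons']}, "
      f"C=C double bonds: {chem['double_bonds']}, "
      f"fully reduced: {chem['fully_reduced']}")
print(f"  backbone SMILES: {backbone_to_linear_notation(bb, policy='first')}")

# 'x' marks an A domain whose substrate prediction is unresolved; '?'
# marks a module lacking an A domain; the SMILES string draws the chain
# still bound to the carrier protein as a thioester (terminal S).
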