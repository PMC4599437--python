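# Methods

This note documents the models, rules and numerical choices behind
`bgcphylo`, and what the tests do and do not establish.

## Inventory notation and data model

The packaged inventory (`src/bgcphylo/data/herbidospora_table2.tsv`)
transcribes the published cluster table of the five *Herbidospora* type
strains: one row per multidomain ORF, with the domain organization in the
assembly-line notation (`/` between domains, `-` between module groups,
substrate subscripts on A/AT, parentheses for tentative calls, `...` for
truncation).  Domain and substrate vocabularies are closed: the thirteen
catalytic domain kinds, the twenty proteinogenic amino acids plus
ornithine, and the three extender CoA units.  Anything else is a parse
error — a deliberate choice so silent typos cannot enter the analysis.
An unannotated `AT` means malonyl-CoA-incorporating; `AT_?` means the
substrate call failed.  Italic (not completely sequenced) genes of the
source table are represented by `...` truncation marks and `>` length
prefixes, since italics do not survive plain text.  The asterisk some ORF
ids carry in the source is preserved as `outside_main_locus` metadata; its
meaning is not defined by the source and it has no computational effect.

Two kinds of transcription repair were needed when building the fixture:
an obvious `KA`→`KS` typo in one module string, and the strain attribution
of a few garbled multi-column rows of the partially sequenced clusters
(these affect only which partial gene belongs to which strain, not any
counted quantity).  The packaged species tree
(`herbidospora_16s_tree_reconstructed.nwk`) is a *reconstructed* fixture:
its ingroup topology follows the described pathway-distribution narrative
and its branch lengths are nominal; treat it as a synthetic stand-in, not
a recomputed 16S phylogeny.

## Module boundary grammar

Assembly lines are segmented on the concatenated domain stream of the
ordered genes.  Genes with a single domain are excluded as atypical
before segmentation.  Ordering: the loading gene first, the TE-bearing
gene last, all else in table order; a gene qualifying as both is treated
as the TE gene.  An A-initiated gene counts as a loading candidate only in
pure NRPS clusters — in PKS/NRPS hybrids stand-alone A/T genes extend the
peptide part downstream of the polyketide chain, so hybrids only promote
CoL-initiated (or bare-AT-initiated) genes.  Two candidates, two TE genes,
or any partially sequenced gene freeze the input order.

Boundary rules (in priority order): a new module opens before every C, KS
and CoL; a gene-initial A/AT opens a module unless it completes an open
C/KS-initiated module still lacking its A/AT (a module split across a
gene boundary); carrier/modification domains and TE extend the open
module; a leading orphan carrier joins the preceding module when one
exists and is otherwise kept as an uncounted remnant; a module consisting
solely of C or KS merges forward when tokens follow and is otherwise
incomplete and uncounted; a sequencing gap (truncated gene end) closes
the open module so nothing merges across missing sequence.  A truncated
module that already carries its AT is counted — this is what makes a
partially sequenced 20-module line report "at least 20" rather than 19.
Clusters with any partial gene report all counts as lower bounds.

Iterative enediyne-class (PksE-like) genes are recognized by KR and DH
*after the last* ACP and exempted from modular counting: their domain
order is not collinear with a product, so they are classified but not
structure-predicted.

This grammar is a reconstruction: the source describes no explicit rules,
only worked counts.  Its justification is that it reproduces every worked
count in the inventory (35, 22, 1+13, 9-from-7-genes, 21-from-7, 9-from-3,
20-lower-bound, 6-module hexaketide) from the table alone.  One sentence
of the source ("five modules" for a cluster whose strings segment to six
and whose product is a hexapeptide) is internally inconsistent and is not
special-cased.

## Backbone prediction

One unit per counted module, in order.  β-keto processing is a pure
function of the module's {KR, DH, ER} subset (none→ketone, KR→hydroxyl,
KR+DH→enoyl, KR+DH+ER→methylene); a DH without KR, or an ER without DH,
is treated as non-functional — this choice is what reproduces the
published "2 double bonds and one hydroxyl" hexaketide.  The loading
module's processing domains are not expressed (its unit is the starter),
which is what reproduces the published nonaketide's "3 double bonds and 5
hydroxyls".  Chain carbons are two per ketide module, loading included
(a heptaketide ⇒ C14).  Ambiguous AT calls propagate as alternative
α-substituent sets ("H-or-methyl" etc.) and require an explicit policy
before a concrete structure is drawn.  Epimerization sets a configuration
flag but does not change the printed residue.  Single-module clusters and
enediyne clusters return an explicit not-predictable marker.  Products
are reported still thioester-bound to the last carrier protein; TE
release/cyclization chemistry, tailoring reactions and stereochemistry
beyond the D/L flag are out of scope.

The SMILES emitter draws the backbone only: starter methyl first,
thioester sulfur last, double bonds without geometry, hydroxyl/keto
states per module.  It is a sketch of connectivity and oxidation state,
not a full natural-product structure.

## Ortholog grouping

Gene-level similarity is 1 − edit distance between domain-kind sequences
normalized by the longer length (edit distance via edlib; a brute-force
DP is the test oracle).  Truncated genes are aligned as an infix of their
partner and normalized by the truncated length, so sequencing gaps are
not penalized as divergence.  Two clusters of different strains link when
they share ≥1 equal closest-homolog accession (version suffixes ignored)
AND the mean similarity over best-matched gene pairs (Hungarian
assignment) is ≥ 0.8 AND at least half the genes of the smaller cluster
are matched.  Groups are connected components.  The 0.8 threshold
operationalizes "identical or almost the same"; the source gives no
number, and the fixture results are insensitive to it over a wide range
(every true ortholog pair in the inventory scores 1.0).

One tie is undecidable from the table content: two strain-specific
single-gene clusters with byte-identical organizations and the same
closest homolog as a third.  The published row alignment (the shared
cluster-id labels of the table) can therefore be supplied as an extra
constraint — labelled clusters with different labels never merge — and
the pipeline uses it for the packaged inventory.  Without it the pure
algorithm merges that one pair (31 groups instead of 32); both behaviours
are tested.  Synthetic-data recovery uses the pure algorithm only.

## Phylogenetics

Distances: p-distance or JC69 (−(3/4)ln(1−4p/3)) with pairwise deletion;
saturation (p ≥ 0.75) is an error, not a clamp.  Neighbor joining is the
standard Saitou–Nei agglomeration with two explicit conventions: Q-matrix
ties break on the lexicographically smallest taxon-pair, and negative
branch lengths clamp to zero with a warning.  It is exact on additive
matrices (tested on 100 random 5–8 taxon trees and against an independent
implementation).  Bootstrap resamples columns with replacement (seeded
generator), rebuilds, and annotates the full-data tree's internal
bipartitions with replicate percentages; majority-rule consensus is not
provided.  Rooting places the root at the midpoint of the outgroup's
pendant edge.  Robinson–Foulds distance is the symmetric difference of
non-trivial bipartitions via dendropy.

## Gain/loss mapping

Dollo parsimony: each pathway is acquired exactly once; the optimum is
unique — gain above the MRCA of the carriers, losses on the stems of the
maximal all-absent subtrees below it.  Events attach to the branch above
a node ("just before" a taxon = its pendant branch).  A brute-force
oracle over every gain placement confirms minimality exhaustively for
all rooted trees on ≤5 leaves × all presence rows, and for sampled 6-leaf
trees.  History classes: *ancestral* (root gain, no loss), *recent*
(pendant-branch gain), *gain-then-loss* (any loss), and *intermediate*
(internal-branch gain, no loss) — the fourth class exists because a
three-way scheme has no slot for a clade-level acquisition that was never
lost.  A Fitch (unordered-parsimony) mode is deliberately not offered:
the single-gain assumption is the model.  The outgroup carries no cluster
data and is pruned before reconstruction.

## Synthetic data

`simulate_inventory` emits five strains with 15–18 clusters each (the
observed range) and plants ortholog groups, module plans and backbone
units.  It reproduces the structural awkwardness the segmenter must
survive — modules split across gene boundaries, trailing bare C/KS,
orphan leading carriers, ~40 % unpredicted A substrates — and perturbs
non-reference members by substrate re-annotation and bounded
modification-domain toggles, calibrated to stay within the grouping
threshold.  It does *not* emulate: hybrid clusters, partial
(truncation-marked) genes, shared accessions between distinct pathways,
or homolog-identity noise — so passing recovery tests show the grammar
and grouping are self-consistent, not that they are robust to annotation
error in real data.  `simulate_presence_evolution` draws one gain branch
uniformly and loses per descendant branch independently; the true event
set may be non-minimal, which is why tests assert the parsimony *bound*
and exact gain recovery only where survivors span the gained clade.
`simulate_alignment` is i.i.d. JC69 along branches.  All generators are
pure functions of (parameters, seed).

## Problem sizes and determinism

Everything the package computes on the packaged inventory is desk-scale
(216 gene rows, 80 clusters, 5 taxa) and deterministic; the test suite's
stochastic components (tree/alignment simulations, bootstrap) use fixed
seeds, with simulation sizes (alignments of 2–10 kb, 100-tree consistency
sweeps, 400–500 simulated characters) chosen to make the tested
properties sharp while keeping the whole suite in seconds.
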