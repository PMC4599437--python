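"""Cross-strain ortholog grouping of gene clusters.

Two clusters from different strains are treated as the same pathway when
(1) at least one cross-strain gene pair shares its closest-homolog
accession, and (2) their domain organizations are identical or almost the
same: the mean token-level similarity over best-matched gene pairs reaches
a threshold (default 0.8), with at least half of the genes of the smaller
cluster matched.  Ortholog groups are the connected components of this
link relation.

Gene-level similarity is one minus the edit distance between the two
domain-kind sequences, normalized by the longer length.  For partially
sequenced genes the truncated kind sequence is aligned as an infix of the
complete one (normalized by the truncated length), so a sequencing gap is
not penalized as divergence.

When a published row alignment is available (an inventory whose shared
``cluster_id`` labels encode the authors' manual ortholog assignment), it
can be supplied as an extra constraint: two labelled clusters with
different labels are never merged.  This resolves ties the table content
cannot (distinct single-gene pathways hitting the same database protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .model import ClusterRecord, GeneRecord, StrainInventory, DOMAIN_KINDS

__all__ = [
    "OrthologGroup",
    "domain_similarity",
    "group_orthologs",
    "classify_sharing",
    "presence_matrix",
    "StrainConflictError",
]

# stable one-character alphabet for edit-distance over domain kinds
_CHAR_OF = {k: chr(ord("A") + i) for i, k in enumerate(sorted(DOMAIN_KINDS))}


class StrainConflictError(ValueError):
    """A strain contributed two clusters to one ortholog component."""


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, ClusterRecord] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def sharing_class(self, n_strains: int) -> str:
        if self.n_members == n_strains:
            return "universal"
        if self.n_members == 1:
            return "specific"
        return "partial"


def _kind_word(gene: GeneRecord) -> str:
    return "".join(_CHAR_OF[k] for k in gene.kinds)


def domain_similarity(a: GeneRecord, b: GeneRecord) -> float:
    """Similarity in [0, 1] between two genes' domain organizations.

    Complete vs complete: 1 - editdistance / max(lengths).  If one gene is
    truncated, its kind sequence is aligned as an infix of the other
    (1 - infix distance / truncated length); symmetric by construction.
    """
    wa, wb = _kind_word(a), _kind_word(b)
    if a.partial != b.partial:
        query, target = (wa, wb) if a.partial else (wb, wa)
        if len(query) > len(target):
            query, target = target, query
        d = edlib.align(query, target, mode="HW")["editDistance"]
        return max(0.0, 1.0 - d / len(query))
    if a.partial and b.partial:
        # both truncated: compare the shorter as an infix of the longer
        query, target = (wa, wb) if len(wa) <= len(wb) else (wb, wa)
        d = edlib.align(query, target, mode="HW")["editDistance"]
        return max(0.0, 1.0 - d / len(query))
    d = edlib.align(wa, wb, mode="NW")["editDistance"]
    return max(0.0, 1.0 - d / max(len(wa), len(wb)))


def _cluster_link(a: ClusterRecord, b: ClusterRecord, threshold: float,
                  min_gene_fraction: float) -> bool:
    accessions_a = {g.closest_homolog_accession for g in a.genes}
    accessions_b = {g.closest_homolog_accession for g in b.genes}
    if not (accessions_a & accessions_b - {""}):
        return False
    sim = np.array(
        [[domain_similarity(ga, gb) for gb in b.genes] for ga in a.genes]
    )
    rows, cols = linear_sum_assignment(-sim)
    matched = sim[rows, cols]
    n_small, n_big = sorted((len(a.genes), len(b.genes)))
    if n_small / n_big < min_gene_fraction:
        return False
    return float(matched.mean()) >= threshold


def group_orthologs(
    inventories: list[StrainInventory],
    threshold: float = 0.8,
    min_gene_fraction: float = 0.5,
    row_labels: str | None = None,
) -> list[OrthologGroup]:
    """Group clusters across strains into orthologous pathways.

    ``row_labels="cluster_id"`` additionally forbids merging two clusters
    whose published row labels differ (see module docstring).  Groups are
    returned in a canonical order independent of strain input order.
    """
    clusters = [(inv.strain_id, c) for inv in inventories for c in inv.clusters]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    for (i, (sa, ca)), (j, (sb, cb)) in combinations(enumerate(clusters), 2):
        if sa == sb:
            continue
        if row_labels == "cluster_id" and ca.cluster_id != cb.cluster_id:
            continue
        if _cluster_link(ca, cb, threshold, min_gene_fraction):
            graph.add_edge(i, j)

    groups: list[OrthologGroup] = []
    for component in nx.connected_components(graph):
        members: dict[str, ClusterRecord] = {}
        for idx in sorted(component):
            strain, cluster = clusters[idx]
            if strain in members:
                raise StrainConflictError(
                    f"strain {strain} contributes both "
                    f"{members[strain].cluster_id} and {cluster.cluster_id} "
                    "to one ortholog component"
                )
            members[strain] = cluster
        groups.append(OrthologGroup(group_id="", members=members))

    groups.sort(key=lambda g: (min(c.cluster_id for c in g.members.values()),
                               min(g.members)))
    for n, g in enumerate(groups, start=1):
        labels = {c.cluster_id for c in g.members.values()}
        g.group_id = labels.pop() if len(labels) == 1 else f"OG{n:02d}"
    return groups


def classify_sharing(groups: list[OrthologGroup], n_strains: int,
                     strain_order: list[str] | None = None) -> dict:
    """Tally groups by phylogenetic distribution class and per-strain
    strain-specific counts."""
    counts = {"universal": 0, "partial": 0, "specific": 0}
    per_strain: dict[str, int] = {s: 0 for s in (strain_order or [])}
    for g in groups:
        cls = g.sharing_class(n_strains)
        counts[cls] += 1
        if cls == "specific":
            (strain,) = g.members
            per_strain[strain] = per_strain.get(strain, 0) + 1
    counts["per_strain_specific"] = per_strain
    return counts


def presence_matrix(groups: list[OrthologGroup],
                    strains: list[str]) -> pd.DataFrame:
    """Binary strains x groups presence/absence matrix."""
    data = {
        g.group_id: [int(s in g.members) for s in strains] for g in groups
    }
    return pd.DataFrame(data, index=pd.Index(strains, name="strain"))
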