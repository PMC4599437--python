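"""Assembly-line ordering and module segmentation.

A module is the unit of one chain-elongation cycle: minimally C/A/T for a
peptide synthetase and KS/AT/ACP for a type-I polyketide synthase.  Large
assembly lines are split over several ORFs, sometimes mid-module, so the
segmenter works on the concatenated domain stream of the ordered genes and
applies a small boundary grammar:

* a new module opens before every C and every KS (and before CoL);
* an A or AT that *begins* a gene opens a new module unless it continues an
  open C/KS-initiated module that still lacks its A/AT (a module split
  across a gene boundary);
* carrier/modification domains (T, ACP, KR, DH, ER, MT, E) and TE extend
  the open module; a leading orphan carrier with no open module is attached
  to the preceding module when one exists, otherwise set aside as an
  uncounted remnant;
* a module consisting solely of C or KS merges forward into the next
  module when tokens follow, and is otherwise left incomplete and not
  counted;
* a truncation boundary (a gene not completely sequenced) closes the open
  module — tokens on the far side of a sequencing gap are never merged.

Iterative enediyne-type PKS genes, recognised by KR/DH domains placed
*after* the ACP, are classified but exempted from modular counting: their
domain order is not collinear with a product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import ClusterRecord, DomainToken, GeneRecord

__all__ = [
    "ModuleRecord",
    "ClusterAssembly",
    "order_genes",
    "segment_modules",
    "count_modules",
    "is_enediyne_like",
    "exclude_single_domain_genes",
]

_OPENERS = {"C", "KS", "CoL"}
_PKS_MODULE_DOMAINS = {"KS", "AT", "ACP", "CoL", "DH", "ER", "KR"}


@dataclass
class ModuleRecord:
    index: int
    kind: str  # "NRPS" | "PKS"
    role: str  # "loading" | "extension" | "termination-bearing" | "incomplete"
    domains: list[DomainToken] = field(default_factory=list)
    spans_genes: list[str] = field(default_factory=list)

    @property
    def domain_kinds(self) -> tuple[str, ...]:
        return tuple(t.kind for t in self.domains)

    @property
    def counted(self) -> bool:
        return self.role != "incomplete"

    @property
    def substrate_token(self) -> DomainToken | None:
        for t in self.domains:
            if t.kind in ("A", "AT"):
                return t
        return None

    @property
    def substrate(self) -> str:
        """Resolved substrate of the module's A/AT: an amino-acid or
        extender name, "unknown" (domain present, call undetermined), or
        "absent" (no A/AT domain)."""
        tok = self.substrate_token
        if tok is None:
            return "absent"
        if tok.substrate is None:
            if tok.ambiguous_set:
                return "|".join(tok.ambiguous_set)
            # an unannotated AT incorporates malonyl-CoA; an unannotated A
            # is simply unpredicted
            return "malonyl" if tok.kind == "AT" else "unknown"
        return tok.substrate


@dataclass
class ClusterAssembly:
    cluster: ClusterRecord
    ordered_genes: list[str]
    modules: list[ModuleRecord]
    complete: bool
    enediyne: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def counted_modules(self) -> list[ModuleRecord]:
        return [m for m in self.modules if m.counted]


def exclude_single_domain_genes(cluster: ClusterRecord) -> list[GeneRecord]:
    """Genes with only a single domain are atypical and excluded from the
    module analysis."""
    return [g for g in cluster.genes if len(g.tokens) > 1]


def is_enediyne_like(cluster: ClusterRecord) -> bool:
    """KR and DH after the ACP is the signature of iterative enediyne
    (PksE-class) synthases."""
    for g in cluster.genes:
        kinds = g.kinds
        if "ACP" in kinds:
            last_acp = len(kinds) - 1 - kinds[::-1].index("ACP")
            after = kinds[last_acp + 1:]
            if "KR" in after and "DH" in after:
                return True
    return False


def _is_loading_start(gene: GeneRecord, cluster_has_ks: bool) -> bool:
    """Would this gene's first module be a chain-initiating (loading)
    module?  CoL-initiated genes always qualify.  A-initiated genes qualify
    only in pure NRPS clusters: in PKS/NRPS hybrids the stand-alone
    A/T genes extend the peptide part downstream of the polyketide chain.
    A bare AT start (no preceding KS) qualifies in PKS context."""
    first = gene.tokens[0].kind
    if first == "CoL":
        return True
    if first == "A":
        return not cluster_has_ks
    if first == "AT":
        return cluster_has_ks
    return False


def order_genes(cluster: ClusterRecord, genes: list[GeneRecord] | None = None
                ) -> list[str]:
    """Order genes along the assembly line.

    The loading gene goes first and the TE-bearing gene last; all other
    genes keep their input (inventory) order.  If a gene both starts with a
    loading module and carries TE, chain release wins and it goes last.
    Ambiguity (two loading candidates or two TE genes) and clusters with
    partially sequenced genes keep the input order, which for partial
    clusters is the only reliable evidence.
    """
    if genes is None:
        genes = list(cluster.genes)
    order = [g.orf_id for g in genes]
    if len(genes) <= 1 or any(g.partial for g in genes):
        return order

    te_genes = [g for g in genes if "TE" in g.kinds]
    cluster_has_ks = any("KS" in g.kinds for g in genes)
    candidates = [
        g for g in genes
        if _is_loading_start(g, cluster_has_ks) and g not in te_genes
    ]

    ordered = list(genes)
    if len(te_genes) == 1:
        ordered.remove(te_genes[0])
        ordered.append(te_genes[0])
    elif len(te_genes) > 1:
        warnings.warn(
            f"{cluster.strain_id}/{cluster.cluster_id}: multiple TE genes; "
            "keeping input order"
        )
        return order
    if len(candidates) == 1:
        ordered.remove(candidates[0])
        ordered.insert(0, candidates[0])
    elif len(candidates) > 1:
        warnings.warn(
            f"{cluster.strain_id}/{cluster.cluster_id}: multiple loading "
            "candidates; keeping input order"
        )
        return order
    return [g.orf_id for g in ordered]


def segment_modules(cluster: ClusterRecord,
                    ordered: list[str] | None = None) -> ClusterAssembly:
    """Segment the ordered, concatenated domain stream into modules."""
    genes = exclude_single_domain_genes(cluster)
    if ordered is None:
        ordered = order_genes(cluster, genes)
    by_id = {g.orf_id: g for g in genes}
    gene_seq = [by_id[o] for o in ordered if o in by_id]

    notes: list[str] = []
    enediyne = is_enediyne_like(cluster)

    modules: list[ModuleRecord] = []
    current: ModuleRecord | None = None

    def close() -> None:
        nonlocal current
        if current is not None:
            modules.append(current)
            current = None

    def open_module(token: DomainToken, orf: str) -> None:
        nonlocal current
        close()
        current = ModuleRecord(index=0, kind="", role="", domains=[token],
                               spans_genes=[orf])

    def extend(token: DomainToken, orf: str) -> None:
        nonlocal current
        assert current is not None
        current.domains.append(token)
        if orf not in current.spans_genes:
            current.spans_genes.append(orf)

    for gene in gene_seq:
        for i, tok in enumerate(gene.tokens):
            at_gene_start = i == 0
            kind = tok.kind
            if kind in _OPENERS:
                if (current is not None
                        and all(t.kind in ("C", "KS") for t in current.domains)):
                    # bare C/KS merges forward into the module it introduces
                    extend(tok, gene.orf_id)
                else:
                    open_module(tok, gene.orf_id)
            elif kind in ("A", "AT"):
                if current is None:
                    open_module(tok, gene.orf_id)
                elif (at_gene_start
                      and any(t.kind in ("A", "AT") for t in current.domains)):
                    # gene-initial A/AT not continuing an A/AT-less module
                    open_module(tok, gene.orf_id)
                else:
                    extend(tok, gene.orf_id)
            else:  # T, ACP, KR, DH, ER, MT, E, TE
                if current is not None:
                    extend(tok, gene.orf_id)
                elif modules and not gene.partial_start:
                    # leading orphan carrier attaches to the previous module
                    modules[-1].domains.append(tok)
                    if gene.orf_id not in modules[-1].spans_genes:
                        modules[-1].spans_genes.append(gene.orf_id)
                    notes.append(
                        f"{gene.orf_id}: leading orphan {kind} absorbed into "
                        "preceding module"
                    )
                else:
                    # remnant on the far side of a sequencing gap
                    current = ModuleRecord(index=0, kind="", role="incomplete",
                                           domains=[tok],
                                           spans_genes=[gene.orf_id])
                    notes.append(
                        f"{gene.orf_id}: orphan {kind} kept as uncounted remnant"
                    )
        if gene.partial_end or gene.partial:
            close()  # never merge across a sequencing gap
    close()

    # roles, kinds, counting
    _assign_roles(modules, notes)

    return ClusterAssembly(
        cluster=cluster,
        ordered_genes=[g.orf_id for g in gene_seq],
        modules=modules,
        complete=not cluster.partial,
        enediyne=enediyne,
        warnings=notes,
    )


def _assign_roles(modules: list[ModuleRecord], notes: list[str]) -> None:
    first_counted = True
    for m in modules:
        kinds = set(t.kind for t in m.domains)
        m.kind = "PKS" if kinds & {"KS", "AT", "ACP", "CoL"} else "NRPS"
        if m.role == "incomplete":
            continue
        if kinds <= {"C", "KS"}:
            m.role = "incomplete"
            notes.append(
                f"trailing bare {'/'.join(sorted(kinds))} module left incomplete"
            )
            continue
        if first_counted:
            if m.kind == "PKS" or m.domains[0].kind in ("A", "AT", "CoL"):
                # the first module of a polyketide chain is its starter;
                # an A-initiated first NRPS module is a loading module
                m.role = "loading"
            else:
                m.role = "extension"
            first_counted = False
        else:
            m.role = "extension"
        if "TE" in kinds:
            m.role = "termination-bearing"
    idx = 0
    for m in modules:
        if m.counted:
            idx += 1
            m.index = idx


def count_modules(assembly: ClusterAssembly) -> dict:
    """Module tallies for one cluster.  ``lower_bound`` is set when any
    gene is partially sequenced ("at least N modules").  Enediyne-class
    clusters are exempt from modular counting."""
    if assembly.enediyne:
        return dict(total=0, nrps=0, pks=0, loading=0, incomplete=0,
                    lower_bound=False, enediyne=True)
    counted = assembly.counted_modules
    return dict(
        total=len(counted),
        nrps=sum(1 for m in counted if m.kind == "NRPS"),
        pks=sum(1 for m in counted if m.kind == "PKS"),
        loading=sum(1 for m in counted if m.role == "loading"),
        incomplete=sum(1 for m in assembly.modules if not m.counted),
        lower_bound=not assembly.complete,
        enediyne=False,
    )
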