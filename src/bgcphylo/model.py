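"""Data model and parser for modular NRPS / type-I PKS cluster inventories.

The inventory notation describes each multidomain megasynthase ORF as a
string of catalytic domains: domains are separated by ``/``, module groups
by ``-``, substrate annotations are appended to adenylation (A) and
acyltransferase (AT) domains (``A_ser``, ``AT_m``), parentheses mark
tentative calls (``A_(lys)``, ``(KS)``), comma lists and ``e(m)``-style
suffixes mark ambiguous alternatives, ``?`` an undetermined substrate, and
leading/trailing ``...`` a truncated (not completely sequenced) gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DomainToken",
    "GeneRecord",
    "ClusterRecord",
    "StrainInventory",
    "DomainParseError",
    "SchemaError",
    "parse_domain_string",
    "parse_domain_notation",
    "format_domain_string",
    "load_cluster_table",
    "load_herbidospora_inventories",
    "load_herbidospora_tree_path",
    "validate_gene",
    "NRPS_DOMAINS",
    "PKS_DOMAINS",
    "DOMAIN_KINDS",
]

# Catalytic domain vocabulary.  C, condensation; A, adenylation; T, thiolation
# (peptidyl carrier); E, epimerization; MT, methyltransferase; CoL, CoA ligase;
# KS, ketosynthase; AT, acyltransferase; DH, dehydratase; ER, enoylreductase;
# KR, ketoreductase; ACP, acyl carrier protein; TE, thioesterase.
NRPS_DOMAINS = frozenset({"C", "A", "T", "E", "MT"})
PKS_DOMAINS = frozenset({"KS", "AT", "DH", "ER", "KR", "ACP", "CoL"})
DOMAIN_KINDS = NRPS_DOMAINS | PKS_DOMAINS | {"TE"}

# Closed substrate vocabulary: proteinogenic amino acids plus ornithine for A
# domains; the three extender CoA units for AT domains.
_AA_BY_CODE = {
    "ala": "alanine", "arg": "arginine", "asn": "asparagine",
    "asp": "aspartate", "cys": "cysteine", "gln": "glutamine",
    "glu": "glutamate", "gly": "glycine", "his": "histidine",
    "ile": "isoleucine", "leu": "leucine", "lys": "lysine",
    "met": "methionine", "phe": "phenylalanine", "pro": "proline",
    "ser": "serine", "thr": "threonine", "trp": "tryptophan",
    "tyr": "tyrosine", "val": "valine", "orn": "ornithine",
}
_CODE_BY_AA = {v: k for k, v in _AA_BY_CODE.items()}

_EXTENDER_BY_CODE = {"m": "methylmalonyl", "e": "ethylmalonyl"}
_CODE_BY_EXTENDER = {v: k for k, v in _EXTENDER_BY_CODE.items()}

TRUNCATION_MARKS = ("...", "…")


class DomainParseError(ValueError):
    """Raised when a domain-organization string cannot be parsed."""


class SchemaError(ValueError):
    """Raised when an inventory table is missing required columns."""


@dataclass(frozen=True)
class DomainToken:
    """A single catalytic domain with optional substrate annotation.

    ``substrate_confidence`` is one of ``firm`` (plain subscript),
    ``tentative`` (parenthesized call), ``ambiguous-set`` (alternative
    substrates listed), or ``none``.  For an ambiguous set, ``substrate``
    holds the primary alternative when the notation named one (``e(m)``)
    and ``None`` for an unordered list (``(m,e)``).
    """

    kind: str
    substrate: str | None = None
    substrate_confidence: str = "none"
    ambiguous_set: tuple[str, ...] | None = None
    tentative_kind: bool = False
    group_start: bool = False

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise DomainParseError(f"unknown domain kind {self.kind!r}")
        if self.substrate is not None and self.kind not in ("A", "AT"):
            raise DomainParseError(
                f"substrate annotation on non-A/AT domain {self.kind!r}"
            )
        if (self.ambiguous_set is not None) != (
            self.substrate_confidence == "ambiguous-set"
        ):
            raise DomainParseError(
                "ambiguous_set must be given exactly when confidence is "
                "'ambiguous-set'"
            )


@dataclass
class GeneRecord:
    """One multidomain NRPS/PKS ORF."""

    orf_id: str
    strain_id: str
    length_aa: int
    tokens: tuple[DomainToken, ...]
    length_is_lower_bound: bool = False
    partial_start: bool = False
    partial_end: bool = False
    closest_homolog_accession: str = ""
    homolog_identity_pct: float = 0.0
    homolog_similarity_pct: float = 0.0
    outside_main_locus: bool = False

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"gene {self.orf_id}: token list must be non-empty")

    @property
    def partial(self) -> bool:
        return self.partial_start or self.partial_end or self.length_is_lower_bound

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(t.kind for t in self.tokens)

    @property
    def domain_string(self) -> str:
        return format_domain_string(
            self.tokens, partial_start=self.partial_start, partial_end=self.partial_end
        )


@dataclass
class ClusterRecord:
    """An ordered collection of megasynthase genes forming one gene cluster."""

    cluster_id: str
    strain_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.strain_id != self.strain_id:
                raise ValueError(
                    f"cluster {self.cluster_id}: gene {g.orf_id} belongs to "
                    f"strain {g.strain_id!r}, not {self.strain_id!r}"
                )

    @property
    def all_kinds(self) -> tuple[str, ...]:
        return tuple(k for g in self.genes for k in g.kinds)

    @property
    def cluster_class(self) -> str:
        """NRPS, PKS, or hybrid (both a ketosynthase chain and an
        adenylation-loaded peptide part present)."""
        kinds = set(self.all_kinds)
        has_pks = "KS" in kinds
        has_nrps = "A" in kinds or "C" in kinds
        if has_pks and has_nrps:
            return "hybrid"
        if has_pks or kinds <= PKS_DOMAINS | {"TE"}:
            return "PKS"
        return "NRPS"

    @property
    def partial(self) -> bool:
        return any(g.partial for g in self.genes)


@dataclass
class StrainInventory:
    strain_id: str
    clusters: list[ClusterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cluster_id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate cluster ids in strain {self.strain_id}")

    def cluster(self, cluster_id: str) -> ClusterRecord:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(f"{self.strain_id}: no cluster {cluster_id!r}")


# ---------------------------------------------------------------------------
# Domain-string parsing


def _parse_substrate(kind: str, sub: str, position: int) -> dict:
    """Interpret the subscript ``sub`` attached to an A or AT domain."""
    vocab = _AA_BY_CODE if kind == "A" else _EXTENDER_BY_CODE

    def lookup(code: str) -> str:
        code = code.strip()
        if code not in vocab:
            raise DomainParseError(
                f"unknown {kind} substrate code {code!r} at domain {position}"
            )
        return vocab[code]

    if sub == "?":
        return dict(substrate="unknown", substrate_confidence="none")
    m = re.fullmatch(r"\(([^()]+)\)", sub)
    if m:
        inner = m.group(1)
        if "," in inner:
            alts = tuple(lookup(c) for c in inner.split(","))
            return dict(
                substrate=None,
                substrate_confidence="ambiguous-set",
                ambiguous_set=alts,
            )
        return dict(substrate=lookup(inner), substrate_confidence="tentative")
    m = re.fullmatch(r"([^()]+)\(([^()]+)\)", sub)
    if m:
        primary = lookup(m.group(1))
        alts = (primary,) + tuple(lookup(c) for c in m.group(2).split(","))
        return dict(
            substrate=primary,
            substrate_confidence="ambiguous-set",
            ambiguous_set=alts,
        )
    return dict(substrate=lookup(sub), substrate_confidence="firm")


def _parse_one_domain(text: str, position: int, group_start: bool) -> DomainToken:
    tentative_kind = False
    m = re.fullmatch(r"\((\w+)\)", text)
    if m:
        tentative_kind = True
        text = m.group(1)
    if "_" in text:
        base, sub = text.split("_", 1)
    else:
        base, sub = text, None
    if base not in DOMAIN_KINDS:
        raise DomainParseError(
            f"unknown domain symbol {base!r} at position {position}"
        )
    extra: dict = {}
    if sub is not None:
        if base not in ("A", "AT"):
            raise DomainParseError(
                f"substrate subscript on {base!r} at position {position}"
            )
        extra = _parse_substrate(base, sub, position)
    return DomainToken(
        kind=base, tentative_kind=tentative_kind, group_start=group_start, **extra
    )


def parse_domain_notation(text: str) -> tuple[tuple[DomainToken, ...], bool, bool]:
    """Parse a full notation string, returning ``(tokens, partial_start,
    partial_end)``.  Truncation marks describe the enclosing gene, not any
    single domain."""
    if text is None:
        raise DomainParseError("empty domain string")
    s = text.strip()
    partial_start = partial_end = False
    for mark in TRUNCATION_MARKS:
        if s.startswith(mark):
            partial_start = True
            s = s[len(mark):]
        if s.endswith(mark):
            partial_end = True
            s = s[: -len(mark)]
    s = s.strip("-/ ")
    if not s:
        raise DomainParseError("empty domain string")
    tokens: list[DomainToken] = []
    position = 0
    for gi, group in enumerate(s.split("-")):
        if not group:
            raise DomainParseError(f"empty module group in {text!r}")
        for di, dom in enumerate(group.split("/")):
            position += 1
            if not dom:
                raise DomainParseError(
                    f"empty domain symbol at position {position} in {text!r}"
                )
            tokens.append(_parse_one_domain(dom, position, gi > 0 and di == 0))
    return tuple(tokens), partial_start, partial_end


def parse_domain_string(text: str) -> tuple[DomainToken, ...]:
    """Parse a domain-organization string into an ordered token tuple."""
    tokens, _, _ = parse_domain_notation(text)
    return tokens


def _format_substrate(token: DomainToken) -> str:
    code_of = _CODE_BY_AA if token.kind == "A" else _CODE_BY_EXTENDER
    if token.substrate == "unknown":
        return "_?"
    if token.substrate_confidence == "firm":
        return f"_{code_of[token.substrate]}"
    if token.substrate_confidence == "tentative":
        return f"_({code_of[token.substrate]})"
    if token.substrate_confidence == "ambiguous-set":
        assert token.ambiguous_set is not None
        if token.substrate is not None:
            others = [a for a in token.ambiguous_set if a != token.substrate]
            return f"_{code_of[token.substrate]}({','.join(code_of[a] for a in others)})"
        return f"_({','.join(code_of[a] for a in token.ambiguous_set)})"
    return ""


def format_domain_string(
    tokens: Sequence[DomainToken],
    partial_start: bool = False,
    partial_end: bool = False,
) -> str:
    """Render tokens back to the canonical notation (round-trips parse)."""
    if not tokens:
        raise ValueError("cannot format an empty token list")
    parts: list[str] = []
    for i, t in enumerate(tokens):
        body = t.kind
        if t.substrate is not None or t.substrate_confidence != "none":
            body += _format_substrate(t)
        if t.tentative_kind:
            body = f"({body})"
        sep = "" if i == 0 else ("-" if t.group_start else "/")
        parts.append(sep + body)
    out = "".join(parts)
    if partial_start:
        out = "..." + out
    if partial_end:
        out = out + "..."
    return out


# ---------------------------------------------------------------------------
# Inventory table IO

REQUIRED_COLUMNS = (
    "strain",
    "cluster_id",
    "orf_id",
    "length_aa",
    "domains",
    "homolog_accession",
    "identity",
    "similarity",
    "flags",
)


def load_cluster_table(path: str | Path) -> list[StrainInventory]:
    """Load a tab-delimited cluster inventory into typed strain inventories.

    Row order within a cluster is preserved: it is the assembly-line hint
    order used downstream when segmenting modules.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    inventories: dict[str, StrainInventory] = {}
    clusters: dict[tuple[str, str], ClusterRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tokens, p_start, p_end = parse_domain_notation(row.domains)
            length = str(row.length_aa).strip()
            lower = length.startswith(">")
            gene = GeneRecord(
                orf_id=row.orf_id,
                strain_id=row.strain,
                length_aa=int(length.lstrip(">")),
                tokens=tokens,
                length_is_lower_bound=lower,
                partial_start=p_start,
                partial_end=p_end,
                closest_homolog_accession=str(row.homolog_accession).split(".")[0],
                homolog_identity_pct=float(row.identity) if row.identity else 0.0,
                homolog_similarity_pct=float(row.similarity) if row.similarity else 0.0,
                outside_main_locus="*" in str(row.flags),
            )
        except (DomainParseError, ValueError) as exc:
            raise DomainParseError(f"{path}, row {i}: {exc}") from exc
        inv = inventories.setdefault(row.strain, StrainInventory(row.strain))
        key = (row.strain, row.cluster_id)
        if key not in clusters:
            clusters[key] = ClusterRecord(row.cluster_id, row.strain)
            inv.clusters.append(clusters[key])
        clusters[key].genes.append(gene)
    return list(inventories.values())


def _data_path(name: str) -> Path:
    return Path(__file__).resolve().parent / "data" / name


def load_herbidospora_inventories() -> list[StrainInventory]:
    """The packaged five-strain *Herbidospora* inventory."""
    return load_cluster_table(_data_path("herbidospora_table2.tsv"))


def load_herbidospora_tree_path() -> Path:
    """Path of the packaged species tree (Newick).

    The ingroup topology was reconstructed from the described pathway
    distribution narrative, not recomputed from 16S sequences; branch
    lengths are nominal.  Treat it as a synthetic stand-in fixture.
    """
    return _data_path("herbidospora_16s_tree_reconstructed.nwk")


# ---------------------------------------------------------------------------
# Advisory validation

FINDING_SINGLE_DOMAIN = "exclude_single_domain"
FINDING_PARTIAL = "partial"
FINDING_UNUSUAL_ORDER = "unusual_order"


def validate_gene(gene: GeneRecord) -> list[str]:
    """Advisory findings: single-domain genes are excluded from module
    analysis; truncated genes make counts lower bounds; an A-C-T start is an
    unusual NRPS domain order (normal is C-A-T)."""
    findings: list[str] = []
    if len(gene.tokens) == 1:
        findings.append(FINDING_SINGLE_DOMAIN)
    if gene.partial:
        findings.append(FINDING_PARTIAL)
    if gene.kinds[:3] == ("A", "C", "T"):
        findings.append(FINDING_UNUSUAL_ORDER)
    return findings
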