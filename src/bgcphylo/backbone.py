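"""Backbone chemistry prediction by the assembly-line (collinearity) rule.

Each counted module contributes one unit to the product, in module order:
an amino-acid residue for NRPS modules (named when the A-domain substrate
is predicted, ``x`` when the A domain is present but its substrate is not,
``?`` when the module lacks an A domain) and a two-carbon ketide unit for
PKS modules.  The unit's beta-keto processing state follows from the
module's optional-domain subset: no KR leaves the ketone; KR alone reduces
it to a hydroxyl; KR+DH eliminate to a C=C double bond (enoyl); KR+DH+ER
reduce fully to a methylene.  A DH or ER without the upstream reductase is
treated as non-functional.  The loading (starter) module's processing
domains are not expressed in the product.  The alpha substituent of each
ketide unit follows the AT substrate: malonyl -> H, methylmalonyl ->
methyl, ethylmalonyl -> ethyl.

Backbones are reported still attached to the carrier protein of the last
module by a thioester bond; chain release/cyclization by TE is not
modelled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .assembly import ClusterAssembly, ModuleRecord
from .model import _CODE_BY_AA  # 3-letter rendering of residue names

__all__ = [
    "PeptideResidue",
    "PolyketideUnit",
    "Backbone",
    "beta_state",
    "alpha_substituent",
    "predict_backbone",
    "product_string",
    "summarize_chemistry",
    "backbone_to_linear_notation",
    "AmbiguityError",
]

_ALPHA_BY_EXTENDER = {
    "malonyl": "H",
    "methylmalonyl": "methyl",
    "ethylmalonyl": "ethyl",
}


class AmbiguityError(ValueError):
    """Raised when a linear structure is requested for a backbone with
    unresolved alternative alpha substituents and no policy was given."""


@dataclass(frozen=True)
class PeptideResidue:
    position: int
    residue: str  # amino-acid name, "x" (substrate unpredicted) or "?" (no A)
    n_methylated: bool = False
    epimerized: bool = False
    tentative: bool = False

    @property
    def display(self) -> str:
        if self.residue in ("x", "?"):
            return self.residue
        short = _CODE_BY_AA[self.residue].capitalize()
        return f"m{short}" if self.n_methylated else short


@dataclass(frozen=True)
class PolyketideUnit:
    position: int
    alpha_substituent: str  # H | methyl | ethyl | "X-or-Y" | unknown
    beta_state: str  # ketone | hydroxyl | enoyl | methylene | starter


@dataclass
class Backbone:
    kind: str  # peptide | polyketide | hybrid
    units: list = field(default_factory=list)
    terminus: str = "thioester-T"
    chain_carbons: int = 0
    not_predictable: bool = False
    enediyne: bool = False
    lower_bound: bool = False


def beta_state(optional_kinds: set[str]) -> str:
    """Beta-keto processing state as a pure function of the module's
    {KR, DH, ER} subset.  DH/ER without KR (or ER without DH) cannot act on
    their substrate and leave the ketone/hydroxyl respectively."""
    has_kr = "KR" in optional_kinds
    has_dh = "DH" in optional_kinds
    has_er = "ER" in optional_kinds
    if not has_kr:
        return "ketone"
    if not has_dh:
        return "hydroxyl"
    if not has_er:
        return "enoyl"
    return "methylene"


def alpha_substituent(module: ModuleRecord) -> str:
    tok = module.substrate_token
    if tok is None or tok.kind != "AT":
        return "unknown"
    if tok.substrate_confidence == "ambiguous-set" and tok.ambiguous_set:
        return "-or-".join(_ALPHA_BY_EXTENDER[a] for a in tok.ambiguous_set)
    if tok.substrate in _ALPHA_BY_EXTENDER:
        return _ALPHA_BY_EXTENDER[tok.substrate]
    if tok.substrate is None:
        return "H"  # an unannotated AT incorporates malonyl-CoA
    return "unknown"  # AT_? — substrate call undetermined


def _peptide_unit(module: ModuleRecord) -> PeptideResidue:
    kinds = set(module.domain_kinds)
    tok = module.substrate_token
    if tok is None or tok.kind != "A":
        residue = "?"
        tentative = False
    elif tok.substrate is None or tok.substrate == "unknown":
        residue = "x"
        tentative = False
    else:
        residue = tok.substrate
        tentative = tok.substrate_confidence == "tentative"
    return PeptideResidue(
        position=module.index,
        residue=residue,
        n_methylated="MT" in kinds,
        epimerized="E" in kinds,
        tentative=tentative,
    )


def predict_backbone(assembly: ClusterAssembly) -> Backbone:
    """One product unit per counted module, in assembly-line order."""
    if not isinstance(assembly, ClusterAssembly):
        raise TypeError("predict_backbone expects a segmented ClusterAssembly")
    counted = assembly.counted_modules

    cls = assembly.cluster.cluster_class
    kind = {"NRPS": "peptide", "PKS": "polyketide", "hybrid": "hybrid"}[cls]
    bb = Backbone(kind=kind, lower_bound=not assembly.complete)

    if assembly.enediyne:
        bb.not_predictable = True
        bb.enediyne = True
        return bb

    for m in counted:
        if m.kind == "PKS":
            state = "starter" if m.role == "loading" else beta_state(
                set(m.domain_kinds)
            )
            bb.units.append(
                PolyketideUnit(
                    position=m.index,
                    alpha_substituent=alpha_substituent(m),
                    beta_state=state,
                )
            )
        else:
            bb.units.append(_peptide_unit(m))

    last = counted[-1] if counted else None
    if last is not None and "TE" in last.domain_kinds:
        bb.terminus = "released-TE"
    elif last is not None and last.kind == "PKS":
        bb.terminus = "thioester-ACP"

    bb.chain_carbons = 2 * sum(
        1
        for m in counted
        if m.kind == "PKS" and {"KS", "AT"} & set(m.domain_kinds)
    )
    if len(counted) <= 1:
        # a single module does not specify a chain; product not predictable
        bb.not_predictable = True
    return bb


def product_string(backbone: Backbone) -> str:
    """Render the presumed product in inventory notation: dash-joined
    residues, ``pk`` for a polyketide stretch, ``?`` for a unit of unknown
    provenance; unpredictable single-module products collapse to their
    substrate in parentheses (known) or a bare ``x``/``?``."""
    if backbone.enediyne:
        return "Enediyne"
    if backbone.not_predictable and len(backbone.units) <= 1:
        if not backbone.units:
            return "?"
        u = backbone.units[0]
        if isinstance(u, PolyketideUnit):
            return "?"
        if u.residue in ("x", "?"):
            return u.residue
        return f"({u.display})"
    parts: list[str] = []
    prev_pk_extension = False
    for u in backbone.units:
        if isinstance(u, PolyketideUnit):
            if u.beta_state == "starter" and u.alpha_substituent == "unknown":
                # CoL-loaded starter of unknown provenance
                parts.append("?")
                prev_pk_extension = False
            else:
                if not prev_pk_extension:
                    parts.append("pk")
                prev_pk_extension = True
        else:
            parts.append(u.display)
            prev_pk_extension = False
    return "-".join(parts)


def summarize_chemistry(backbone: Backbone) -> dict:
    """Feature counts over the predicted backbone.

    Double bonds / hydroxyls / fully reduced positions / ketones are counted
    over non-starter polyketide units; chain carbons are two per ketide
    unit; residue composition tallies named residues and the ``x``/``?``
    placeholders separately.
    """
    pk = [u for u in backbone.units if isinstance(u, PolyketideUnit)]
    ext = [u for u in pk if u.beta_state != "starter"]
    residues = Counter(
        u.display if u.residue not in ("x", "?") else u.residue
        for u in backbone.units
        if isinstance(u, PeptideResidue)
    )
    return dict(
        modules=len(backbone.units),
        chain_carbons=backbone.chain_carbons,
        double_bonds=sum(1 for u in ext if u.beta_state == "enoyl"),
        hydroxyls=sum(1 for u in ext if u.beta_state == "hydroxyl"),
        ketones=sum(1 for u in ext if u.beta_state == "ketone"),
        fully_reduced=sum(1 for u in ext if u.beta_state == "methylene"),
        residue_composition=dict(residues),
        lower_bound=backbone.lower_bound,
    )


_BRANCH = {"H": "", "methyl": "(C)", "ethyl": "(CC)"}


def _resolve_alpha(unit: PolyketideUnit, policy: str | None) -> str:
    alpha = unit.alpha_substituent
    if alpha in _BRANCH:
        return alpha
    if "-or-" in alpha:
        if policy is None:
            raise AmbiguityError(
                f"ambiguous alpha substituent at position {unit.position}: "
                f"{alpha}; pass policy='first' to take the first alternative"
            )
        if policy == "first":
            return alpha.split("-or-")[0]
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    # undetermined AT substrate: draw the unsubstituted chain
    return "H"


def backbone_to_linear_notation(backbone: Backbone, policy: str | None = None
                                ) -> str:
    """Linear structure of the backbone.

    Polyketide (and the polyketide part is required to be the whole chain)
    backbones are emitted as a SMILES string of the carbon chain, starter
    methyl first, terminated as a thioester to a placeholder sulfur.
    Peptide backbones are emitted as dash-joined residues with ``NMe-`` and
    ``D-`` prefixes for N-methylation and epimerization.
    """
    if backbone.kind == "peptide":
        out = []
        for u in backbone.units:
            if not isinstance(u, PeptideResidue):
                continue
            name = u.residue if u.residue in ("x", "?") else \
                _CODE_BY_AA[u.residue].capitalize()
            if u.n_methylated:
                name = "NMe-" + name
            if u.epimerized:
                name = "D-" + name
            out.append(name)
        return "-".join(out)

    pk = [u for u in backbone.units if isinstance(u, PolyketideUnit)]
    if not pk:
        raise ValueError("no polyketide units to draw")
    ambiguous = [u.position for u in pk if "-or-" in u.alpha_substituent]
    if ambiguous and policy is None:
        raise AmbiguityError(
            f"ambiguous alpha substituents at positions {ambiguous}"
        )
    starter, extensions = pk[0], pk[1:]
    smiles = "C" + _BRANCH[_resolve_alpha(starter, policy)]
    for u in extensions:
        branch = _BRANCH[_resolve_alpha(u, policy)]
        if u.beta_state == "ketone":
            smiles += "C(=O)C" + branch
        elif u.beta_state == "hydroxyl":
            smiles += "C(O)C" + branch
        elif u.beta_state == "methylene":
            smiles += "CC" + branch
        elif u.beta_state == "enoyl":
            smiles += "C=C" + branch
        else:
            raise ValueError(f"unexpected beta state {u.beta_state!r}")
    smiles += "C(=O)S"
    return smiles
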