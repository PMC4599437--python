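"""End-to-end analysis: parse -> segment -> predict -> group -> tree ->
gain/loss events, with a machine-readable report.

The species tree may be supplied as a rooted Newick file (with or without
an outgroup leaf) or built from a 16S alignment by neighbor joining with
bootstrap; the report records which route was taken.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO

from . import assembly as asm
from . import backbone as bb
from . import gainloss as gl
from . import orthologs as og
from . import phylo
from .model import (StrainInventory, load_cluster_table, validate_gene,
                    FINDING_SINGLE_DOMAIN)

__all__ = ["AnalysisReport", "run_analysis", "analyze_inventories"]

DEFAULTS = dict(threshold=0.8, min_gene_fraction=0.5, row_labels=True,
                bootstrap=0, seed=0, outgroup=None)


@dataclass
class AnalysisReport:
    strain_counts: dict  # strain -> {NRPS, hybrid, PKS, total}
    module_counts: dict  # (strain, cluster) -> count dict
    products: dict       # (strain, cluster) -> product string
    groups: list         # [{group_id, members, sharing_class}]
    sharing: dict
    presence: pd.DataFrame
    tree_newick: str
    tree_source: str
    events: list
    event_classes: dict
    branch_events: pd.DataFrame
    exclusions: list
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dict(
            config=self.config,
            strain_counts=self.strain_counts,
            module_counts={f"{s}/{c}": v
                           for (s, c), v in self.module_counts.items()},
            products={f"{s}/{c}": v for (s, c), v in self.products.items()},
            groups=self.groups,
            sharing=self.sharing,
            presence=self.presence.to_dict(),
            tree=self.tree_newick.strip(),
            tree_source=self.tree_source,
            events=[
                dict(group_id=e.group_id, gain=e.gain_branch,
                     losses=list(e.loss_branches))
                for e in self.events
            ],
            event_classes=self.event_classes,
            branch_events=self.branch_events.to_dict(orient="index"),
            exclusions=self.exclusions,
        )
        return json.dumps(payload, indent=2, sort_keys=True)


def analyze_inventories(
    inventories: list[StrainInventory],
    tree=None,
    msa=None,
    outgroup: str | None = None,
    threshold: float = 0.8,
    min_gene_fraction: float = 0.5,
    row_labels: bool = True,
    bootstrap_replicates: int = 0,
    seed: int = 0,
    config: dict | None = None,
) -> AnalysisReport:
    """Run the full comparative analysis on in-memory inventories."""
    exclusions: list[str] = []
    strain_counts: dict = {}
    module_counts: dict = {}
    products: dict = {}

    for inv in inventories:
        tally = {"NRPS": 0, "hybrid": 0, "PKS": 0, "total": 0}
        for cluster in inv.clusters:
            cls = cluster.cluster_class
            tally[cls] += 1
            tally["total"] += 1
            for gene in cluster.genes:
                findings = validate_gene(gene)
                if FINDING_SINGLE_DOMAIN in findings:
                    exclusions.append(
                        f"{inv.strain_id}/{cluster.cluster_id}/{gene.orf_id}: "
                        "single-domain gene excluded"
                    )
            assembled = asm.segment_modules(cluster)
            module_counts[(inv.strain_id, cluster.cluster_id)] = \
                asm.count_modules(assembled)
            products[(inv.strain_id, cluster.cluster_id)] = \
                bb.product_string(bb.predict_backbone(assembled))
        strain_counts[inv.strain_id] = tally

    groups = og.group_orthologs(
        inventories, threshold=threshold,
        min_gene_fraction=min_gene_fraction,
        row_labels="cluster_id" if row_labels else None,
    )
    strains = [inv.strain_id for inv in inventories]
    sharing = og.classify_sharing(groups, len(strains), strain_order=strains)
    presence = og.presence_matrix(groups, strains)

    if tree is not None:
        species_tree = tree
        tree_source = "supplied"
    elif msa is not None:
        species_tree = phylo.nj_tree(phylo.msa_distances(msa))
        if bootstrap_replicates:
            species_tree = phylo.bootstrap(msa, bootstrap_replicates, seed)
        tree_source = "neighbor-joining from alignment"
    else:
        raise ValueError("either a tree or an alignment must be provided")
    if outgroup is not None:
        species_tree = phylo.root_with_outgroup(species_tree, outgroup,
                                                prune_outgroup=True)

    events = [
        gl.dollo_map(species_tree,
                     {s: int(presence.loc[s, g.group_id]) for s in strains},
                     group_id=g.group_id)
        for g in groups
    ]
    branch_events, event_classes = gl.summarize_events(events, species_tree)

    return AnalysisReport(
        strain_counts=strain_counts,
        module_counts=module_counts,
        products=products,
        groups=[
            dict(group_id=g.group_id, members=sorted(g.members),
                 sharing_class=g.sharing_class(len(strains)))
            for g in groups
        ],
        sharing=sharing,
        presence=presence,
        tree_newick=phylo.tree_to_newick(species_tree),
        tree_source=tree_source,
        events=events,
        event_classes=event_classes,
        branch_events=branch_events,
        exclusions=exclusions,
        config=config or {},
    )


def run_analysis(config_path: str | Path, outdir: str | Path | None = None
                 ) -> AnalysisReport:
    """Run the analysis from a TOML config and write report files.

    Config keys: ``table`` (required), ``tree`` or ``msa``, ``outgroup``,
    ``threshold``, ``min_gene_fraction``, ``row_labels``, ``bootstrap``,
    ``seed``, ``outdir``.
    """
    config_path = Path(config_path)
    with open(config_path, "rb") as fh:
        cfg = {**DEFAULTS, **tomllib.load(fh)}
    base = config_path.parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    inventories = load_cluster_table(_resolve(cfg["table"]))
    tree = phylo.load_tree(_resolve(cfg["tree"])) if cfg.get("tree") else None
    msa = AlignIO.read(_resolve(cfg["msa"]), "fasta") if cfg.get("msa") else None

    report = analyze_inventories(
        inventories, tree=tree, msa=msa, outgroup=cfg.get("outgroup"),
        threshold=cfg["threshold"],
        min_gene_fraction=cfg["min_gene_fraction"],
        row_labels=bool(cfg["row_labels"]),
        bootstrap_replicates=int(cfg["bootstrap"]),
        seed=int(cfg["seed"]),
        config={k: v for k, v in cfg.items() if v is not None},
    )

    outdir = Path(outdir) if outdir else _resolve(cfg.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    pd.DataFrame(report.groups).to_csv(outdir / "groups.tsv", sep="\t",
                                       index=False)
    pd.DataFrame(
        [{"strain": s, "cluster": c, "product": p}
         for (s, c), p in sorted(report.products.items())]
    ).to_csv(outdir / "products.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"group_id": e.group_id, "gain": e.gain_branch,
          "losses": ";".join(e.loss_branches),
          "class": report.event_classes[e.group_id]}
         for e in report.events]
    ).to_csv(outdir / "events.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(report.tree_newick)
    return report
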