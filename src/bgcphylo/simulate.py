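"""Seeded generators of synthetic inputs with known ground truth.

Three generators emulate the three kinds of real input the pipeline
consumes, at the scale of the five-strain study they stand in for:

* ``simulate_inventory`` — multi-strain cluster inventories with planted
  ortholog groups and per-cluster module plans (default five strains with
  15-18 clusters each, the observed range).  Domain strings include the
  awkward realities of real assembly lines: modules split across gene
  boundaries, trailing bare condensation domains, orphan leading carrier
  domains, and roughly 40 % of A-domain substrates left unpredicted.
* ``simulate_presence_evolution`` — presence/absence characters evolved on
  a rooted tree under a single-gain / multiple-independent-loss process.
* ``simulate_alignment`` — nucleotide alignments evolved site-independently
  under the one-parameter (JC69) substitution model.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

from .gainloss import EventMap, branch_id
from .model import GeneRecord, ClusterRecord, StrainInventory, parse_domain_string

__all__ = [
    "SimulationTruth",
    "simulate_inventory",
    "simulate_presence_evolution",
    "simulate_alignment",
]

_AA_CODES = ("ser", "gly", "asp", "asn", "lys", "thr", "val", "leu",
             "phe", "tyr", "ala", "orn")
_BETA_DOMAINS = {
    "ketone": (),
    "hydroxyl": ("KR",),
    "enoyl": ("DH", "KR"),
    "methylene": ("DH", "ER", "KR"),
}


@dataclass
class SimulationTruth:
    seed: int
    planned_modules: dict = field(default_factory=dict)   # (strain, cid) -> counts
    true_backbones: dict = field(default_factory=dict)    # (strain, cid) -> units
    true_groups: dict = field(default_factory=dict)       # (strain, cid) -> group
    true_tree: dendropy.Tree | None = None
    true_events: list[EventMap] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Inventories


def _nrps_plan(rng: np.random.Generator, n_modules: int) -> list[list[str]]:
    """Per-module domain lists; substrates encoded in the domain symbol."""
    plan: list[list[str]] = []
    loading = rng.random() < 0.4
    for i in range(n_modules):
        sub = f"_{rng.choice(_AA_CODES)}" if rng.random() < 0.6 else ""
        mod = (["C"] if (i > 0 or not loading) else []) + [f"A{sub}"]
        if rng.random() < 0.1:
            mod.append("MT")
        mod.append("T")
        if i == n_modules - 1 and rng.random() < 0.1:
            mod.append("E")
        plan.append(mod)
    if rng.random() < 0.8:
        plan[-1].append("TE")
    return plan


def _pks_plan(rng: np.random.Generator, n_modules: int) -> list[list[str]]:
    plan: list[list[str]] = []
    for i in range(n_modules):
        r = rng.random()
        sub = "" if r < 0.65 else ("_m" if r < 0.85 else
                                   ("_e" if r < 0.92 else "_?"))
        mod = ["KS", f"AT{sub}"]
        if i > 0:
            state = rng.choice(list(_BETA_DOMAINS))
            mod.extend(_BETA_DOMAINS[state])
        mod.append("ACP")
        plan.append(mod)
    if rng.random() < 0.8:
        plan[-1].append("TE")
    return plan


def _split_genes(rng: np.random.Generator,
                 plan: list[list[str]], cls: str) -> list[list[str]]:
    """Split a module plan into gene token lists, occasionally across
    module boundaries to exercise the segmenter's merge rules."""
    n = len(plan)
    max_genes = min(6, n)
    n_genes = 1 + int(rng.integers(0, max_genes))
    cuts = sorted(rng.choice(np.arange(1, n), size=min(n_genes - 1, n - 1),
                             replace=False)) if n > 1 and n_genes > 1 else []
    genes: list[list[str]] = []
    start = 0
    for cut in list(cuts) + [n]:
        genes.append([d for m in plan[start:cut] for d in m])
        start = cut
    genes = [g for g in genes if g]

    first_is_loading = plan[0][0].startswith("A")
    if (cls == "NRPS" and first_is_loading and len(genes) >= 2
            and rng.random() < 0.3):
        # trailing bare C: the next module's C closes the previous gene
        for k in range(1, len(genes)):
            if genes[k] and genes[k][0] == "C":
                genes[k - 1].append(genes[k].pop(0))
                break
    if cls == "PKS" and len(genes) >= 2 and rng.random() < 0.3:
        # cross-gene module continuation: break after AT or DH
        for k in range(1, len(genes)):
            g = genes[k]
            for brk in ("DH", "AT"):
                hits = [i for i, d in enumerate(g) if d.startswith(brk)]
                if hits and hits[0] + 1 < len(g) and hits[0] > 0:
                    genes[k - 1] = genes[k - 1] + g[: hits[0] + 1]
                    genes[k] = g[hits[0] + 1:]
                    break
            else:
                continue
            break
    if (cls == "NRPS" and first_is_loading and len(genes) >= 2
            and rng.random() < 0.15):
        genes[1].insert(0, "T")  # orphan leading carrier, absorbed upstream
    if rng.random() < 0.1:
        genes[-1].append("C" if cls == "NRPS" else "KS")  # uncounted decoy
    return [g for g in genes if g]


def _perturb(rng: np.random.Generator, genes: list[list[str]],
             cls: str) -> list[list[str]]:
    """0-2 substrate re-annotations per gene plus at most one
    modification-domain toggle on long genes; keeps the domain-kind edit
    distance within the grouping threshold."""
    out = []
    for g in genes:
        g = list(g)
        slots = [i for i, d in enumerate(g)
                 if d.startswith("A_") or d == "A" or d.startswith("AT")]
        for i in rng.choice(slots, size=min(len(slots), int(rng.integers(0, 3))),
                            replace=False) if slots else []:
            if cls == "NRPS" or g[i].startswith("A_") or g[i] == "A":
                sub = f"_{rng.choice(_AA_CODES)}" if rng.random() < 0.6 else ""
                g[i] = f"A{sub}"
            else:
                g[i] = "AT" + ("" if rng.random() < 0.6 else "_m")
        if len(g) >= 10 and cls == "NRPS" and rng.random() < 0.3:
            t_positions = [i for i, d in enumerate(g) if d == "T"]
            if t_positions:
                g.insert(int(rng.choice(t_positions)), "MT")
        out.append(g)
    return out


def _plan_counts(plan: list[list[str]], cls: str) -> dict:
    pks = sum(1 for m in plan if m[0] == "KS" or m[0] == "CoL")
    return dict(total=len(plan), pks=pks, nrps=len(plan) - pks)


def simulate_inventory(
    n_strains: int = 5,
    clusters_per_strain: tuple[int, int] = (15, 18),
    module_count_range: tuple[int, int] = (1, 12),
    seed: int = 0,
) -> tuple[list[StrainInventory], SimulationTruth]:
    """Multi-strain inventories with planted ortholog groups.

    Every generated domain string parses; module segmentation of each
    cluster recovers the planned counts; ortholog grouping at the default
    threshold recovers the planted group labels exactly.
    """
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    strains = [f"strain{i + 1:02d}" for i in range(n_strains)]
    targets = {s: int(rng.integers(clusters_per_strain[0],
                                   clusters_per_strain[1] + 1))
               for s in strains}
    emitted = {s: [] for s in strains}

    gid = 0
    while any(len(emitted[s]) < targets[s] for s in strains):
        gid += 1
        open_strains = [s for s in strains if len(emitted[s]) < targets[s]]
        r = rng.random()
        if r < 0.3 and len(open_strains) >= 2:
            k = int(rng.integers(2, len(open_strains) + 1))
            members = list(rng.choice(open_strains, size=k, replace=False))
        elif r < 0.6:
            members = list(open_strains)
        else:
            members = [str(rng.choice(open_strains))]

        cls = str(rng.choice(["NRPS", "PKS"], p=[0.55, 0.45]))
        lo, hi = module_count_range
        n_modules = int(rng.integers(lo, hi + 1))
        plan = (_nrps_plan if cls == "NRPS" else _pks_plan)(rng, n_modules)
        genes_ref = _split_genes(rng, plan, cls)

        for s in sorted(members):
            cid = f"{s}-cl{len(emitted[s]) + 1:02d}"
            genes_tokens = _perturb(rng, genes_ref, cls) \
                if s != sorted(members)[0] else [list(g) for g in genes_ref]
            genes = []
            for r_i, toks in enumerate(genes_tokens):
                text = "/".join(toks)
                genes.append(
                    GeneRecord(
                        orf_id=f"{cid}-g{r_i + 1}",
                        strain_id=s,
                        length_aa=100 * len(toks),
                        tokens=parse_domain_string(text),
                        closest_homolog_accession=f"SIM{gid:04d}R{r_i}",
                    )
                )
            emitted[s].append(ClusterRecord(cid, s, genes))
            truth.true_groups[(s, cid)] = f"G{gid:04d}"
            truth.planned_modules[(s, cid)] = _plan_counts(plan, cls)
            units = []
            for d in (tok for g in genes_tokens for tok in g):
                if d.startswith("AT"):
                    units.append("pk")
                elif d.startswith("A_"):
                    units.append(d.split("_", 1)[1])
                elif d == "A":
                    units.append("x")
            truth.true_backbones[(s, cid)] = units

    inventories = [StrainInventory(s, emitted[s]) for s in strains]
    return inventories, truth


# ---------------------------------------------------------------------------
# Presence/absence evolution


def simulate_presence_evolution(
    tree: dendropy.Tree,
    n_groups: int,
    loss_prob_per_branch: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[EventMap]]:
    """Single-gain / multiple-loss evolution of pathway presence.

    Each group gains on a uniformly chosen branch and then loses
    independently on each branch below the gain with the given
    probability; groups extinct in all leaves are redrawn.
    """
    if not 0 <= loss_prob_per_branch < 1:
        raise ValueError("loss_prob_per_branch must be in [0, 1)")
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder_node_iter())
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    leaf_set = frozenset(leaves)

    rows = {}
    events: list[EventMap] = []
    for g in range(n_groups):
        while True:
            gain_node = nodes[int(rng.integers(0, len(nodes)))]
            lost_nodes: list[dendropy.Node] = []
            present_leaves: set[str] = set()

            def walk(node: dendropy.Node, alive: bool) -> None:
                if alive and node is not gain_node and \
                        rng.random() < loss_prob_per_branch:
                    lost_nodes.append(node)
                    alive = False
                if node.is_leaf():
                    if alive:
                        present_leaves.add(node.taxon.label)
                    return
                for child in node.child_nodes():
                    walk(child, alive)

            walk(gain_node, True)
            if present_leaves:
                break
        group_id = f"G{g + 1:04d}"
        rows[group_id] = [int(lf in present_leaves) for lf in leaves]
        states = {}
        for node in tree.preorder_node_iter():
            nid = branch_id(node, tree)
            node_leaves = ({lf.taxon.label for lf in node.leaf_iter()}
                           if not node.is_leaf() else {node.taxon.label})
            states[nid] = "present" if node_leaves & present_leaves else "absent"
        events.append(
            EventMap(
                group_id=group_id,
                gain_branch=branch_id(gain_node, tree),
                loss_branches=tuple(sorted(branch_id(n, tree)
                                           for n in lost_nodes)),
                ancestral_states=states,
                leaf_set=leaf_set,
            )
        )
    matrix = pd.DataFrame(rows, index=pd.Index(leaves, name="strain"))
    return matrix, events


# ---------------------------------------------------------------------------
# Sequence evolution


def simulate_alignment(
    tree: dendropy.Tree,
    length: int,
    seed: int = 0,
    model: str = "JC69",
) -> MultipleSeqAlignment:
    """Evolve a nucleotide alignment along the tree under JC69: a uniform
    random root sequence, and on each branch of length t a substitution
    probability per site of (3/4)(1 - exp(-4t/3)) to a uniformly chosen
    different base."""
    if model.upper() != "JC69":
        raise ValueError("only the JC69 model is implemented")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=length)

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        parent = seqs[id(node.parent_node)]
        child = parent.copy()
        hit = rng.random(length) < p_sub
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + shift) % 4
        seqs[id(node)] = child

    records = [
        SeqRecord(Seq("".join(bases[seqs[id(lf)]])), id=lf.taxon.label,
                  description="")
        for lf in tree.leaf_node_iter()
    ]
    records.sort(key=lambda r: r.id)
    return MultipleSeqAlignment(records)
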