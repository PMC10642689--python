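"""Gene-family history simulation along a species tree with a ground-truth ledger.

The opsin family complement evolves along each species-tree branch by a
Poisson process with per-lineage event rates (tandem duplication, dispersed
duplication, retrotransposition, loss, single-gene translocation, and
autosome–Z chromosome fusion). Events may also be *planted* at fixed branches
to build histories with a known, deterministic truth. Every event is recorded
in an :class:`EventLedger` which can be replayed to the exact extant gene
complement, and from which the true per-family gene genealogies are read off.

Gene positions are tracked as abstract *slots*: background gene ``i`` of a
chromosome occupies slot ``i``; opsin copies occupy fractional slots, so the
number of intervening background genes between two copies is implied by their
slot interval. Chromosome fusion relabels a whole autosome onto the Z with a
slot offset that preserves relative gene order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import dendropy

from opsinkit.config import SimulationConfig, PlantedEvent

FUSION_SLOT_OFFSET = 10_000.0  # fused-autosome genes order after native Z genes

EVENT_KINDS = (
    "duplication_tandem",
    "duplication_dispersed",
    "duplication_retro",
    "loss",
    "translocation",
    "chromosome_fusion",
)
DUPLICATION_KINDS = EVENT_KINDS[:3]


@dataclass
class Event:
    kind: str
    branch: str          # species-tree branch, named by its child node label
    time: float          # depth from species-tree root
    family: str | None = None
    source_gene: str | None = None
    product_gene: str | None = None
    source_chrom: str | None = None
    dest_chrom: str | None = None


@dataclass
class GNode:
    """A segment of a gene lineage between two branching points."""

    uid: int
    family: str
    t_start: float
    omega: float
    parent: "GNode | None" = None
    children: list = field(default_factory=list)
    t_end: float | None = None
    gene_id: str | None = None   # set on extant leaves
    species: str | None = None
    alive: bool = True           # False once lost

    @property
    def length(self) -> float:
        return (self.t_end if self.t_end is not None else self.t_start) - self.t_start


@dataclass
class GeneCopy:
    copy_uid: int
    family: str
    chrom: str
    slot: float
    exon_count: int
    strand: str
    tandem_gap: bool      # emitted with the tandem intergenic spacing
    gnode: GNode
    gene_id: str | None = None


@dataclass
class EventLedger:
    """Ground truth of a simulated history."""

    events: list[Event]
    extant: dict[str, list[GeneCopy]]        # species -> copies
    roots: dict[str, GNode]                  # family -> genealogy root
    fused: dict[str, list[str]]              # species -> fused autosome names
    tree: dendropy.Tree
    cfg: SimulationConfig

    def duplications(self) -> list[Event]:
        return [e for e in self.events if e.kind in DUPLICATION_KINDS]

    def copy_number(self, species: str, family: str) -> int:
        return sum(1 for c in self.extant[species] if c.family == family)


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def _branch_name(node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def simulate_gene_family_history(tree: dendropy.Tree, cfg: SimulationConfig
                                 ) -> EventLedger:
    """Simulate duplications/losses/translocations/fusions with known truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    depths = _node_depths(tree)
    autosomes = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    chroms = autosomes + ["chrZ"]
    n_bg = cfg.background_genes_per_chrom

    uid_counter = itertools.count()
    gnode_counter = itertools.count()
    events: list[Event] = []
    extant: dict[str, list[GeneCopy]] = {}
    fused_by_species: dict[str, list[str]] = {}

    planted_by_branch: dict[str, list[PlantedEvent]] = {}
    for ev in cfg.planted_events:
        planted_by_branch.setdefault(ev.branch, []).append(ev)

    # one ancestral copy per family, each family on its own autosome
    roots: dict[str, GNode] = {}
    root_copies: list[GeneCopy] = []
    for i, fam in enumerate(cfg.families):
        gn = GNode(next(gnode_counter), fam, 0.0, cfg.omega_background)
        roots[fam] = gn
        root_copies.append(
            GeneCopy(next(uid_counter), fam, autosomes[i % len(autosomes)],
                     slot=float(n_bg // 2) + 0.5, exon_count=cfg.n_introns + 1,
                     strand="+", tandem_gap=False, gnode=gn)
        )

    rate_names = ("rate_tandem", "rate_dispersed", "rate_retro", "rate_loss",
                  "rate_translocation")
    kind_of_rate = dict(zip(rate_names, EVENT_KINDS[:5]))

    def random_slot() -> float:
        return float(rng.uniform(0, n_bg)) if n_bg else float(rng.uniform(0, 10))

    def branch_gnode(parent_gn: GNode, t: float, omega=None) -> GNode:
        child = GNode(next(gnode_counter), parent_gn.family, t,
                      omega if omega is not None else parent_gn.omega,
                      parent=parent_gn)
        parent_gn.children.append(child)
        return child

    def split_gnode(copy: GeneCopy, t: float, new_omega=None) -> GNode:
        """Close the copy's open segment at t; continue it and fork a new one."""
        gn = copy.gnode
        gn.t_end = t
        copy.gnode = branch_gnode(gn, t)
        return branch_gnode(gn, t, omega=new_omega)

    def apply_event(kind: str, t: float, branch: str, copies: list[GeneCopy],
                    fused: list[str], planted: PlantedEvent | None = None) -> None:
        if kind == "chromosome_fusion":
            candidates = [c for c in autosomes if c not in fused]
            if not candidates:
                return
            if planted is not None and planted.dest_chrom:
                src = planted.dest_chrom
            else:
                src = candidates[int(rng.integers(len(candidates)))]
            if src in fused:
                return
            fused.append(src)
            for c in copies:
                if c.chrom == src:
                    c.chrom = "chrZ"
                    c.slot += FUSION_SLOT_OFFSET
            events.append(Event(kind, branch, t, source_chrom=src, dest_chrom="chrZ"))
            return
        if not copies:
            return
        if planted is not None:
            fam_copies = [c for c in copies if c.family == planted.family]
            if not fam_copies:
                return
            fam_copies.sort(key=lambda c: (c.chrom, c.slot))
            src = fam_copies[min(planted.copy_index, len(fam_copies) - 1)]
        else:
            src = copies[int(rng.integers(len(copies)))]
        dest_override = planted.dest_chrom if planted is not None else None

        if kind == "loss":
            src.gnode.t_end = t
            src.gnode.alive = False
            copies.remove(src)
            events.append(Event(kind, branch, t, family=src.family,
                                source_gene=f"u{src.copy_uid}",
                                source_chrom=src.chrom))
            return
        if kind == "translocation":
            old = src.chrom
            choices = [c for c in chroms if c != old and c not in fused]
            dest = dest_override or choices[int(rng.integers(len(choices)))]
            src.chrom = dest
            src.slot = random_slot() + (FUSION_SLOT_OFFSET if dest in fused else 0)
            events.append(Event(kind, branch, t, family=src.family,
                                source_gene=f"u{src.copy_uid}",
                                source_chrom=old, dest_chrom=dest))
            return

        # duplications
        if kind == "duplication_tandem":
            dest, exons = src.chrom, src.exon_count
            slot = src.slot + 1e-4 * (1 + next(uid_counter) % 100)
            tandem = True
        elif kind == "duplication_dispersed":
            dest = dest_override or src.chrom
            exons = src.exon_count
            tandem = False
            slot = random_slot()
            if dest == src.chrom:
                while abs(slot - src.slot) < 2.0:  # land >=2 genes away
                    slot = random_slot()
        else:  # duplication_retro: intronless, different chromosome
            exons = 1
            if dest_override:
                dest = dest_override
            else:
                choices = [c for c in chroms if c != src.chrom and c not in fused]
                dest = choices[int(rng.integers(len(choices)))]
            slot = random_slot()
            tandem = False
        new_omega = cfg.omega_retro if kind == "duplication_retro" else None
        new_gn = split_gnode(src, t, new_omega=new_omega)
        new_copy = GeneCopy(next(uid_counter), src.family, dest, slot,
                            exons, "+" if rng.random() < 0.5 else "-",
                            tandem, new_gn)
        copies.append(new_copy)
        events.append(Event(kind, branch, t, family=src.family,
                            source_gene=f"u{src.copy_uid}",
                            product_gene=f"u{new_copy.copy_uid}",
                            source_chrom=src.chrom, dest_chrom=dest))

    def walk(node, copies: list[GeneCopy], fused: list[str]) -> None:
        if node.parent_node is not None:
            t0, t1 = depths[node.parent_node], depths[node]
            branch = _branch_name(node)
            sched: list[tuple[float, str, PlantedEvent | None]] = []
            planted = planted_by_branch.get(branch, [])
            for i, pev in enumerate(planted):
                tau = t0 + (t1 - t0) * (i + 1) / (len(planted) + 1)
                sched.append((tau, pev.kind, pev))
            rate_total = sum(getattr(cfg, rn) for rn in rate_names) + cfg.rate_fusion
            if rate_total > 0:
                weights = np.array(
                    [getattr(cfg, rn) for rn in rate_names] + [cfg.rate_fusion]
                )
                probs = weights / weights.sum()
                t = t0
                while True:
                    t += rng.exponential(1.0 / rate_total)
                    if t >= t1:
                        break
                    kind = EVENT_KINDS[int(rng.choice(6, p=probs))]
                    sched.append((t, kind, None))
            for t, kind, pev in sorted(sched, key=lambda x: x[0]):
                apply_event(kind, t, branch, copies, fused, planted=pev)
        if node.is_leaf():
            species = node.taxon.label
            t_tip = depths[node]
            copies.sort(key=lambda c: (c.chrom, c.slot))
            idx: dict[str, int] = {}
            for c in copies:
                k = idx.get(c.family, 0) + 1
                idx[c.family] = k
                c.gene_id = f"{species}_{c.family}_{k}"
                c.gnode.t_end = t_tip
                c.gnode.gene_id = c.gene_id
                c.gnode.species = species
            extant[species] = copies
            fused_by_species[species] = fused
            return
        t = depths[node]
        for c in copies:
            c.gnode.t_end = t
        for child in node.child_nodes():
            child_copies = []
            for c in copies:
                gn = branch_gnode(c.gnode, t)
                child_copies.append(replace(c, copy_uid=next(uid_counter), gnode=gn))
            walk(child, child_copies, list(fused))

    walk(tree.seed_node, root_copies, [])
    _prune_dead(roots)
    return EventLedger(events, extant, roots, fused_by_species, tree, cfg)


def _prune_dead(roots: dict[str, GNode]) -> None:
    """Drop genealogy segments with no extant descendants."""

    def has_extant(gn: GNode) -> bool:
        if gn.gene_id is not None:
            return gn.alive
        gn.children = [c for c in gn.children if has_extant(c)]
        return bool(gn.children)

    for gn in roots.values():
        has_extant(gn)


def genealogy_newick(root: GNode, use_time: bool = True) -> str | None:
    """True gene tree of one family as newick; None if <2 extant genes.

    Unary chains (speciation segments where one side died) are suppressed by
    summing their lengths.
    """

    def render(gn: GNode, extra: float) -> str | None:
        if gn.gene_id is not None:
            return f"{gn.gene_id}:{gn.length + extra:.8f}"
        kids = gn.children
        if not kids:
            return None
        if len(kids) == 1:
            return render(kids[0], extra + gn.length)
        parts = [render(k, 0.0) for k in kids]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            # child collapsed away; splice through
            lab, ln = parts[0].rsplit(":", 1)
            return f"{lab}:{float(ln) + gn.length + extra:.8f}"
        return f"({','.join(parts)}):{gn.length + extra:.8f}"

    def count_leaves(gn: GNode) -> int:
        if gn.gene_id is not None:
            return 1
        return sum(count_leaves(c) for c in gn.children)

    if count_leaves(root) < 2:
        return None
    body = render(root, 0.0)
    if body is None:
        return None
    lab = body.rsplit(":", 1)[0]
    return f"{lab};"


def true_gene_trees(ledger: EventLedger) -> dict[str, dendropy.Tree]:
    """Per-family true gene genealogies as rooted dendropy trees."""
    out = {}
    for fam, root in ledger.roots.items():
        nwk = genealogy_newick(root)
        if nwk is None:
            continue
        t = dendropy.Tree.get(data=nwk, schema="newick",
                              preserve_underscores=True)
        t.is_rooted = True
        out[fam] = t
    return out


def replay_ledger(ledger: EventLedger) -> dict[str, dict[str, int]]:
    """Replay events to per-species family copy numbers (independent of the
    simulator's extant bookkeeping; used to check ledger consistency)."""
    tree = ledger.tree
    counts: dict[str, dict[str, int]] = {}
    events_by_branch: dict[str, list[Event]] = {}
    for e in ledger.events:
        events_by_branch.setdefault(e.branch, []).append(e)

    def walk(node, state: dict[str, int]) -> None:
        if node.parent_node is not None:
            for e in sorted(events_by_branch.get(_branch_name(node), []),
                            key=lambda e: e.time):
                if e.kind in DUPLICATION_KINDS:
                    state[e.family] = state.get(e.family, 0) + 1
                elif e.kind == "loss":
                    state[e.family] = state.get(e.family, 0) - 1
        if node.is_leaf():
            counts[node.taxon.label] = dict(state)
            return
        for child in node.child_nodes():
            walk(child, dict(state))

    walk(tree.seed_node, {fam: 1 for fam in ledger.cfg.families})
    return counts
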