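"""Mechanistic classification of opsin duplicates.

Combines exon structure (retrogene detection: an intronless duplicate of a
multi-intron parent points to retrotransposition), genomic position (tandem /
proximal / dispersed / translocated relative to the parent), chromosome
category (autosome vs Z vs W linkage), and gene-order synteny (whole-block
co-migration distinguishes an autosome–Z fusion from a single-gene
translocation). Classification uses only coordinates and exon structure,
never sequence content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from opsinkit.genome import AnnotatedGenome, GeneModel

LOCATIONS = ("tandem", "proximal", "dispersed_same_chromosome", "translocated")


@dataclass
class DuplicateClassification:
    duplicate_id: str
    parent_id: str
    mechanism: str                     # retro | dna
    location: str                      # one of LOCATIONS
    linkage: str                       # autosome | Z | W | unknown
    translocation_mode: str = "not_applicable"   # fusion | single_gene
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.translocation_mode != "not_applicable" \
                and self.location != "translocated":
            raise ValueError("translocation_mode set for a non-translocated "
                             "duplicate")

    @property
    def summary_mechanism(self) -> str:
        """Collapse to the event-level mechanism vocabulary.

        tandem -> "tandem"; same-chromosome non-tandem -> "dispersed";
        translocated retro -> "retro"; translocated DNA copies split into
        "fusion" vs "translocation" by the synteny mode.
        """
        if self.location == "tandem":
            return "tandem"
        if self.location in ("proximal", "dispersed_same_chromosome"):
            return "dispersed"
        if self.mechanism == "retro":
            return "retro"
        return "fusion" if self.translocation_mode == "fusion" else "translocation"


def detect_retrogene(duplicate: GeneModel, parent: GeneModel,
                     min_parent_exons: int = 3) -> tuple[str, str]:
    """Retro iff the duplicate is single-exon and the parent has introns.

    A single-exon parent makes the intron-presence criterion inapplicable;
    such pairs are classified ``dna`` with an explanatory note rather than
    guessed as retro.
    """
    if duplicate.exon_count == 1 and parent.exon_count >= min_parent_exons:
        note = "duplicate intronless, parent has %d introns" % (parent.exon_count - 1)
        if duplicate.chrom != parent.chrom:
            note += "; different chromosome (supporting)"
        return "retro", note
    if duplicate.exon_count == 1 and parent.exon_count == 1:
        return "dna", "indeterminate: single-exon parent"
    return "dna", "duplicate retains introns"


def _intervening_genes(a: GeneModel, b: GeneModel, genome: AnnotatedGenome) -> int:
    lo, hi = min(a.end, b.end), max(a.start, b.start)
    return sum(1 for g in genome.genes.values()
               if g.chrom == a.chrom and g.gene_id not in (a.gene_id, b.gene_id)
               and g.start >= lo and g.end <= hi)


def classify_duplicate_location(duplicate: GeneModel, parent: GeneModel,
                                genome: AnnotatedGenome,
                                proximal_bp: int = 100_000,
                                max_tandem_intervening: int = 1) -> str:
    """tandem / proximal / dispersed_same_chromosome / translocated."""
    if duplicate.chrom != parent.chrom:
        return "translocated"
    if _intervening_genes(duplicate, parent, genome) <= max_tandem_intervening:
        return "tandem"
    gap = max(duplicate.start, parent.start) - min(duplicate.end, parent.end)
    if gap <= proximal_bp:
        return "proximal"
    return "dispersed_same_chromosome"


def classify_sex_linkage(gene: GeneModel, genome: AnnotatedGenome) -> str:
    """Return the chromosome category: autosome, Z, W, or unknown."""
    if gene.chrom not in genome.chromosomes:
        raise ValueError(f"chromosome {gene.chrom} absent from table")
    cat = genome.chromosomes[gene.chrom].category
    return "unknown" if cat == "unplaced" else cat


def _flanking(gene_id: str, genome: AnnotatedGenome, window: int) -> list[GeneModel]:
    gene = genome.genes[gene_id]
    on_chrom = genome.genes_on(gene.chrom)
    idx = next(i for i, g in enumerate(on_chrom) if g.gene_id == gene_id)
    out: list[GeneModel] = []
    lo, hi = idx - 1, idx + 1
    while len(out) < window and (lo >= 0 or hi < len(on_chrom)):
        if lo >= 0:
            out.append(on_chrom[lo]); lo -= 1
        if len(out) < window and hi < len(on_chrom):
            out.append(on_chrom[hi]); hi += 1
    return out


def classify_translocation_mode(duplicate: GeneModel,
                                focal_genome: AnnotatedGenome,
                                comparator_genome: AnnotatedGenome,
                                window: int = 10, min_comigrated: int = 5
                                ) -> tuple[str, list[str]]:
    """fusion vs single_gene for a translocated duplicate.

    A chromosome fusion moves the duplicate's whole neighborhood with it, so
    the genes flanking the duplicate in the focal genome sit, in a comparator
    genome lacking the event, together on a *different* (autosomal)
    chromosome in conserved relative order — they co-migrated. After a
    single-gene translocation the duplicate's new neighbors are natives of
    the destination chromosome: their comparator orthologs are on the same
    chromosome as in the focal genome, i.e. nothing co-migrated. Fusion is
    called when at least ``min_comigrated`` of the ``window`` flanking genes
    co-migrated from one shared source chromosome in conserved order.
    Ortholog identity comes from ``ortholog_group`` gene attributes.
    """
    evidence: list[str] = []
    flank = _flanking(duplicate.gene_id, focal_genome, window)
    flank = [g for g in flank if g.attributes.get("ortholog_group")]
    if len(flank) < window:
        evidence.append(f"window shrunk to {len(flank)} genes (chromosome end)")
    comp_by_group = {
        g.attributes.get("ortholog_group"): g
        for g in comparator_genome.genes.values()
        if g.attributes.get("ortholog_group")
    }
    migrated: list[tuple[GeneModel, GeneModel]] = []   # (focal, comparator)
    for g in flank:
        comp = comp_by_group.get(g.attributes["ortholog_group"])
        if comp is not None and comp.chrom != g.chrom:
            migrated.append((g, comp))
    n_mig = len(migrated)
    evidence.append(f"{n_mig}/{len(flank)} flanking genes co-migrated")
    if n_mig >= min_comigrated:
        source_chroms = {c.chrom for _, c in migrated}
        if len(source_chroms) == 1 and _order_conserved(migrated):
            evidence.append(f"shared source chromosome "
                            f"{next(iter(source_chroms))}, order conserved")
            return "fusion", evidence
        evidence.append("co-migrated genes lack a shared ordered source block")
    return "single_gene", evidence


def _order_conserved(pairs: list[tuple[GeneModel, GeneModel]]) -> bool:
    """Focal vs comparator gene order conserved (block inversion allowed)."""
    order = [c.start for f, c in sorted(pairs, key=lambda p: p[0].start)]
    increasing = all(a <= b for a, b in zip(order, order[1:]))
    decreasing = all(a >= b for a, b in zip(order, order[1:]))
    return increasing or decreasing


def classify_duplicate(duplicate: GeneModel, parent: GeneModel,
                       genome: AnnotatedGenome,
                       comparator_genome: AnnotatedGenome | None = None,
                       proximal_bp: int = 100_000,
                       window: int = 10, min_comigrated: int = 5
                       ) -> DuplicateClassification:
    """Full mechanistic classification of one duplicate/parent pair."""
    if duplicate.chrom not in genome.chromosomes \
            or parent.chrom not in genome.chromosomes:
        raise ValueError("duplicate and parent must be placed on chromosomes "
                         "of the same genome")
    mechanism, note = detect_retrogene(duplicate, parent)
    location = classify_duplicate_location(duplicate, parent, genome,
                                           proximal_bp=proximal_bp)
    linkage = classify_sex_linkage(duplicate, genome)
    mode = "not_applicable"
    evidence = [note]
    if location == "translocated":
        if comparator_genome is not None:
            mode, ev = classify_translocation_mode(
                duplicate, genome, comparator_genome,
                window=window, min_comigrated=min_comigrated)
            evidence.extend(ev)
        else:
            mode = "single_gene"
            evidence.append("no comparator genome: defaulting to single_gene")
    return DuplicateClassification(duplicate.gene_id, parent.gene_id,
                                   mechanism, location, linkage, mode, evidence)
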