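"""Genome, gene-model and annotation containers plus FASTA/GFF3/TSV round-trip I/O.

Coordinates are 0-based half-open in memory. GFF3 on disk is written and read
as 1-based inclusive, per the format specification. Chromosome metadata
(autosome / Z / W category) travels in a plain TSV with columns
``chromosome``, ``length``, ``category``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHROM_CATEGORIES = ("autosome", "Z", "W", "unplaced")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    category: str = "autosome"  # autosome | Z | W | unplaced

    def __post_init__(self):
        if self.category not in CHROM_CATEGORIES:
            raise ValueError(f"unknown chromosome category {self.category!r}")


@dataclass
class GeneModel:
    """A protein-coding gene model with ordered exon intervals.

    ``exons`` are genomic [start, end) intervals in ascending order regardless
    of strand; ``cds`` is the spliced coding sequence in transcription
    direction (reverse-complemented for '-' strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: str = ""
    attributes: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def protein(self) -> str:
        aa = str(Seq(self.cds).translate())
        return aa[:-1] if aa.endswith("*") else aa

    @property
    def has_start(self) -> bool:
        return self.cds[:3] == "ATG"

    @property
    def has_stop(self) -> bool:
        return self.cds[-3:] in ("TAA", "TAG", "TGA")

    @property
    def has_internal_stop(self) -> bool:
        return "*" in str(Seq(self.cds).translate())[:-1]

    @property
    def complete(self) -> bool:
        return (
            len(self.cds) % 3 == 0
            and self.has_start
            and self.has_stop
            and not self.has_internal_stop
        )

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unordered")
            prev_end = e


@dataclass
class AnnotatedGenome:
    """One species' assembly: chromosome sequences, metadata and gene models."""

    species: str
    sequences: dict[str, str]
    chromosomes: dict[str, Chromosome]
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add_gene(self, gene: GeneModel) -> None:
        gene.validate()
        if gene.chrom not in self.sequences:
            raise ValueError(f"{gene.gene_id}: unknown chromosome {gene.chrom}")
        if gene.end > len(self.sequences[gene.chrom]):
            raise ValueError(f"{gene.gene_id}: extends beyond {gene.chrom}")
        self.genes[gene.gene_id] = gene

    def spliced_cds(self, gene: GeneModel) -> str:
        seq = self.sequences[gene.chrom]
        cds = "".join(seq[s:e] for s, e in gene.exons)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: g.start,
        )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_chromosome_table(genome: AnnotatedGenome, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(c.name, c.length, c.category) for c in genome.chromosomes.values()],
        columns=["chromosome", "length", "category"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_chromosome_table(path: str | os.PathLike) -> dict[str, Chromosome]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.chromosome: Chromosome(row.chromosome, int(row.length), row.category)
        for row in df.itertuples()
    }


def write_gff3(genome: AnnotatedGenome, path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS features, converting to 1-based inclusive."""
    lines = ["##gff-version 3"]
    for chrom in genome.chromosomes.values():
        lines.append(f"##sequence-region {chrom.name} 1 {chrom.length}")
    for gene in sorted(genome.genes.values(), key=lambda g: (g.chrom, g.start)):
        attrs = ";".join(
            [f"ID={gene.gene_id}"]
            + [f"{k}={v}" for k, v in sorted(gene.attributes.items())]
        )
        g1, g2 = gene.start + 1, gene.end  # 0-based half-open -> 1-based inclusive
        row = [gene.chrom, "opsinkit", "gene", str(g1), str(g2), ".", gene.strand, "."]
        lines.append("\t".join(row + [attrs]))
        mrna_id = f"{gene.gene_id}.t1"
        lines.append(
            "\t".join(
                [gene.chrom, "opsinkit", "mRNA", str(g1), str(g2), ".", gene.strand, ".",
                 f"ID={mrna_id};Parent={gene.gene_id}"]
            )
        )
        exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
        # CDS phase bookkeeping in transcription order
        phase = 0
        for i, (s, e) in enumerate(exons, 1):
            for feat, extra in (("exon", "."), ("CDS", str(phase))):
                lines.append(
                    "\t".join(
                        [gene.chrom, "opsinkit", feat, str(s + 1), str(e), ".",
                         gene.strand, extra if feat == "CDS" else ".",
                         f"ID={mrna_id}.{feat}{i};Parent={mrna_id}"]
                    )
                )
            phase = (3 - ((e - s) - phase) % 3) % 3
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike, sequences: dict[str, str] | None = None
              ) -> dict[str, GeneModel]:
    """Parse a GFF3 file back into GeneModel objects (1-based -> 0-based)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for gf in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(gf, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
        exons.sort()
        attrs = {k: v[0] for k, v in gf.attributes.items() if k != "ID"}
        gene = GeneModel(
            gene_id=gf.id, chrom=gf.seqid, strand=gf.strand, exons=exons,
            attributes=attrs,
        )
        if sequences is not None:
            seq = sequences[gf.seqid]
            cds = "".join(seq[s:e] for s, e in exons)
            if gf.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            gene.cds = cds
        genes[gf.id] = gene
    return genes


def load_genome(species: str, fasta_path, gff3_path, chrom_table_path) -> AnnotatedGenome:
    sequences = read_fasta(fasta_path)
    chromosomes = read_chromosome_table(chrom_table_path)
    genome = AnnotatedGenome(species, sequences, chromosomes)
    genome.genes = read_gff3(gff3_path, sequences)
    return genome
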