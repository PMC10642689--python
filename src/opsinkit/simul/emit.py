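"""Emit synthetic genomes (FASTA + GFF3 + chromosome TSV) from a ledger.

Each species' chromosomes are laid out gene-by-gene in slot order: shared
background genes (with stable ``ortholog_group`` labels across species, the
in-dataset proxy for genome-wide orthology) interleaved with the opsin copies
of the simulated history. Tandem duplicates sit adjacent to their parent with
the configured ~6 kb spacing; retro and translocated copies sit on their
ledger-specified chromosome; a fused autosome's genes all appear on the neo-Z
in preserved relative order. Multi-exon genes get GT..AG introns at codon
(phase-0) boundaries.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from opsinkit.genome import (
    AnnotatedGenome,
    Chromosome,
    GeneModel,
    write_fasta,
    write_gff3,
    write_chromosome_table,
)
from opsinkit.simul.history import EventLedger, FUSION_SLOT_OFFSET, true_gene_trees
from opsinkit.simul.codon_evolve import random_root_cds

STOP = "TAA"
_BG_CDS_LEN = 100  # codons per background gene


class LayoutOverflowError(ValueError):
    """Chromosome gene content does not fit the requested fixed length."""


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


MIN_EXON_CODONS = 10


def _split_exons(cds: str, n_exons: int, intron_length: int,
                 rng: np.random.Generator):
    """Split a CDS into n_exons pieces at codon boundaries, with introns.

    Exons are at least MIN_EXON_CODONS codons long (uniform over such
    compositions). Returns (gene_sequence_forward, exon intervals relative
    to gene start).
    """
    n_codons = len(cds) // 3
    n_exons = min(n_exons, max(1, n_codons // MIN_EXON_CODONS))
    if n_exons > 1:
        # cuts with >= MIN_EXON_CODONS spacing: shrink, sample, re-inflate
        slack = n_codons - n_exons * MIN_EXON_CODONS
        raw = np.sort(rng.choice(np.arange(slack + 1), size=n_exons - 1,
                                 replace=True))
        cuts = [int(r + (i + 1) * MIN_EXON_CODONS) for i, r in enumerate(raw)]
    else:
        cuts = []
    pieces, prev = [], 0
    for c in list(cuts) + [n_codons]:
        pieces.append(cds[prev * 3:c * 3])
        prev = c
    seq_parts, exons, pos = [], [], 0
    for i, piece in enumerate(pieces):
        if i > 0:
            intron = "GT" + _random_nt(rng, intron_length - 4) + "AG"
            seq_parts.append(intron)
            pos += len(intron)
        exons.append((pos, pos + len(piece)))
        seq_parts.append(piece)
        pos += len(piece)
    return "".join(seq_parts), exons


def emit_genomes(ledger: EventLedger, sequences: dict[str, str],
                 cfg=None, out_dir: str | os.PathLike | None = None,
                 chromosome_length: int | None = None
                 ) -> dict[str, AnnotatedGenome]:
    """Build AnnotatedGenome objects (and optionally write files) per species.

    ``sequences`` maps gene_id -> CDS (without terminal stop), as produced by
    :func:`evolve_codon_sequences`.
    """
    cfg = cfg or ledger.cfg
    autosomes = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    n_bg = cfg.background_genes_per_chrom
    genomes: dict[str, AnnotatedGenome] = {}

    for sp_i, (species, copies) in enumerate(sorted(ledger.extant.items())):
        rng = np.random.default_rng([cfg.seed % (2**31), 11, sp_i])
        fused = ledger.fused.get(species, [])
        chrom_names = [c for c in autosomes if c not in fused] + ["chrZ"]
        genome = AnnotatedGenome(species, {}, {})

        for chrom in chrom_names:
            # ordered items on this chromosome: (sort_key, kind, payload)
            items: list[tuple[float, str, object]] = []
            source_chroms = [chrom] if chrom != "chrZ" else ["chrZ"] + fused
            for k, src in enumerate(source_chroms):
                offset = 0.0 if k == 0 else FUSION_SLOT_OFFSET * k
                for i in range(n_bg):
                    items.append((offset + i, "bg", f"bg_{src}_{i:02d}"))
            for copy in copies:
                if copy.chrom == chrom:
                    items.append((copy.slot, "opsin", copy))
            items.sort(key=lambda x: x[0])

            parts: list[str] = []
            pos = 0
            for key, kind, payload in items:
                if kind == "opsin" and getattr(payload, "tandem_gap", False):
                    gap = int(cfg.tandem_spacing * rng.uniform(0.8, 1.2))
                else:
                    gap = max(50, int(rng.exponential(cfg.intergenic_mean)))
                parts.append(_random_nt(rng, gap))
                pos += gap
                if kind == "bg":
                    cds = random_root_cds(_BG_CDS_LEN, rng) + STOP
                    gene_seq, rel_exons = cds, [(0, len(cds))]
                    gene_id = f"{species}_{payload}"
                    attrs = {"ortholog_group": str(payload), "gene_type": "background"}
                    strand = "+"
                else:
                    copy = payload
                    cds = sequences[copy.gene_id] + STOP
                    gene_seq, rel_exons = _split_exons(
                        cds, copy.exon_count, cfg.intron_length, rng)
                    gene_id = copy.gene_id
                    attrs = {"family": copy.family, "gene_type": "opsin"}
                    strand = copy.strand
                if strand == "-":
                    from Bio.Seq import Seq
                    L = len(gene_seq)
                    gene_seq = str(Seq(gene_seq).reverse_complement())
                    rel_exons = sorted((L - b, L - a) for a, b in rel_exons)
                exons = [(pos + a, pos + b) for a, b in rel_exons]
                parts.append(gene_seq)
                pos += len(gene_seq)
                genome.genes[gene_id] = GeneModel(
                    gene_id, chrom, strand, exons, cds=cds, attributes=attrs)
            parts.append(_random_nt(rng, max(50, int(rng.exponential(cfg.intergenic_mean)))))
            seq = "".join(parts)
            if chromosome_length is not None:
                if len(seq) > chromosome_length:
                    raise LayoutOverflowError(
                        f"{species}/{chrom}: content {len(seq)} nt exceeds "
                        f"fixed length {chromosome_length}")
                seq = seq + _random_nt(rng, chromosome_length - len(seq))
            genome.sequences[chrom] = seq
            category = "Z" if chrom == "chrZ" else "autosome"
            genome.chromosomes[chrom] = Chromosome(chrom, len(seq), category)

        for gene in genome.genes.values():
            gene.validate()
        genomes[species] = genome

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for species, genome in genomes.items():
            write_fasta(genome.sequences, out / f"{species}.fa")
            write_gff3(genome, out / f"{species}.gff3")
            write_chromosome_table(genome, out / f"{species}.chroms.tsv")
        ledger.tree.write(path=str(out / "species_tree.nwk"), schema="newick",
                          suppress_rooting=True)
        with open(out / "truth_ledger.tsv", "w") as fh:
            fh.write("kind\tbranch\ttime\tfamily\tsource_gene\tproduct_gene\t"
                     "source_chrom\tdest_chrom\n")
            for e in ledger.events:
                fh.write("\t".join(str(x) if x is not None else "." for x in (
                    e.kind, e.branch, f"{e.time:.6f}", e.family, e.source_gene,
                    e.product_gene, e.source_chrom, e.dest_chrom)) + "\n")
        for fam, gt in true_gene_trees(ledger).items():
            gt.write(path=str(out / f"genetree_{fam}.nwk"), schema="newick",
                     suppress_rooting=True)
    return genomes
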