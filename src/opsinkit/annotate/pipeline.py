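"""Iterative homology annotation: search -> ORF reconstruction -> re-seed.

Round 1 searches the original seed proteins against every genome; each later
round adds every *complete* reconstructed gene of acceptable protein length
to the seed set and repeats, so divergent copies reachable only through an
intermediate homolog are picked up transitively. The recovered gene set is
monotone non-decreasing across rounds, and iteration stops at a fixed point
or at ``max_rounds``.
"""

from __future__ import annotations

from dataclasses import dataclass

from opsinkit.annotate.search import (
    translated_search_multi,
    merge_hits_to_loci,
    six_frame_translations,
)
from opsinkit.annotate.orf import reconstruct_orf
from opsinkit.annotate.classify import classify_opsin, OpsinGene
from opsinkit.genome import GeneModel


@dataclass
class AnnotationThresholds:
    min_hit_score: float = 80.0
    min_model_score: float = 150.0
    kmer: int = 5
    min_seeds: int = 2           # k-mer seeds required to extend a window
    min_promote_len: int = 250   # "appropriate protein length" window (aa)
    max_promote_len: int = 600
    max_locus_gap: int = 1500
    flank: int = 1000
    intron_penalty: float = 15.0
    min_intron: int = 30
    classify_margin: float = 0.05


def _overlaps(model: GeneModel, others: list[GeneModel], min_frac: float = 0.3) -> bool:
    for o in others:
        if o.chrom != model.chrom:
            continue
        inter = min(model.end, o.end) - max(model.start, o.start)
        if inter > min_frac * min(model.end - model.start, o.end - o.start):
            return True
    return False


def annotate_genome(seeds: dict[str, str], sequences: dict[str, str],
                    thresholds: AnnotationThresholds,
                    existing: list[GeneModel] | None = None,
                    species: str = "sp", frames=None) -> list[GeneModel]:
    """One annotation round of one genome; returns only newly found models."""
    existing = list(existing or [])
    exclude = [(g.chrom, g.start, g.end) for g in existing]
    hits = translated_search_multi(dict(seeds), sequences,
                                   min_score=thresholds.min_hit_score,
                                   k=thresholds.kmer,
                                   min_seeds=thresholds.min_seeds,
                                   frames=frames, exclude=exclude)
    new_models: list[GeneModel] = []
    for loc in merge_hits_to_loci(hits, max_gap=thresholds.max_locus_gap):
        span = GeneModel("_locus", loc["chrom"], loc["strand"],
                         [(loc["start"], max(loc["start"] + 1, loc["end"]))])
        if _overlaps(span, existing) or _overlaps(span, new_models):
            continue
        candidates = []
        seen_q = set()
        for h in sorted(loc["hits"], key=lambda h: -h.score):
            if h.query_id in seen_q:
                continue
            seen_q.add(h.query_id)
            m = reconstruct_orf(loc, sequences, seeds[h.query_id],
                                flank=thresholds.flank,
                                min_score=thresholds.min_model_score,
                                intron_penalty=thresholds.intron_penalty,
                                min_intron=thresholds.min_intron)
            if m is not None:
                m.attributes["seed"] = h.query_id
                candidates.append(m)
            if len(candidates) >= 2:
                break
        if not candidates:
            continue
        best = max(candidates, key=lambda m: float(m.attributes["alignment_score"]))
        if _overlaps(best, existing) or _overlaps(best, new_models):
            continue
        best.gene_id = f"{species}_opsin_{len(existing) + len(new_models) + 1:03d}"
        new_models.append(best)
    return new_models


def iterative_annotation(seeds: dict[str, str],
                         genomes: dict[str, dict[str, str]],
                         max_rounds: int = 2,
                         thresholds: AnnotationThresholds | None = None,
                         references: dict[str, tuple[str, str]] | None = None,
                         ) -> dict[str, list[OpsinGene]]:
    """Annotate opsin genes in every genome by iterated homology search.

    Parameters
    ----------
    seeds : seed id -> protein sequence (round-1 queries).
    genomes : species -> {chromosome: sequence}.
    references : labeled proteins for classification (id -> (class, seq));
        when omitted, genes are returned with class "unassigned".

    Returns species -> list of OpsinGene.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    thresholds = thresholds or AnnotationThresholds()
    found: dict[str, list[GeneModel]] = {sp: [] for sp in genomes}
    seed_pool = dict(seeds)
    frames_cache = {sp: six_frame_translations(seq)
                    for sp, seq in genomes.items()}
    for _ in range(max_rounds):
        added = 0
        for sp, sequences in sorted(genomes.items()):
            new = annotate_genome(seed_pool, sequences, thresholds,
                                  existing=found[sp], species=sp,
                                  frames=frames_cache[sp])
            found[sp].extend(new)
            added += len(new)
            for m in new:
                prot = m.protein
                if (m.complete
                        and thresholds.min_promote_len <= len(prot)
                        <= thresholds.max_promote_len):
                    seed_pool.setdefault(f"{m.gene_id}", prot)
        if added == 0:
            break
    out: dict[str, list[OpsinGene]] = {}
    for sp, models in found.items():
        genes = []
        for m in models:
            if references is not None:
                label, ev = classify_opsin(m, references,
                                           margin=thresholds.classify_margin)
            else:
                label, ev = "unassigned", {}
            genes.append(OpsinGene(m, label, ev))
        out[sp] = genes
    return out
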