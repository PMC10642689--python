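"""Within-species paralog gene-pair linkage analysis.

Paralog pairs are reciprocal best hits (RBH) in an all-vs-all protein
comparison, retained only when the two genes lie on the same chromosome,
query coverage is >= 70% and percent identity >= 65% — the filters used to
build a background of pairs comparable to the tightly linked blue-opsin
paralogs of lycaenid butterflies. The focal pair's intergenic distance is
then placed as an empirical percentile within the background distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from opsinkit.annotate.search import make_protein_aligner, _alignment_stats
from opsinkit.genome import GeneModel


@dataclass
class ParalogPair:
    gene_a: str           # ordered by genomic position (a upstream)
    gene_b: str
    chrom: str
    coverage: float
    identity: float
    intergenic_bp: int

    def __post_init__(self):
        if self.intergenic_bp < 0:
            raise ValueError("intergenic distance must be >= 0")


def intergenic_distance(a: GeneModel, b: GeneModel) -> int:
    """bp between the end of the upstream gene and the start of the
    downstream gene; 0 for overlapping genes; strand-agnostic; symmetric."""
    if a.chrom != b.chrom:
        raise ValueError("genes on different chromosomes")
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end)


def find_paralog_pairs(proteome: dict[str, tuple[str, GeneModel]],
                       min_coverage: float = 0.70,
                       min_identity: float = 65.0) -> list[ParalogPair]:
    """RBH paralog pairs under the linkage-background filters.

    ``proteome`` maps gene id -> (protein sequence, gene model with
    coordinates). Each gene joins at most one retained pair (greedy by
    alignment score). Output is sorted by (chrom, position) and invariant
    to input order.
    """
    ids = sorted(proteome)
    if len(ids) < 2:
        return []
    aligner = make_protein_aligner("local")
    n = len(ids)
    score = np.full((n, n), -np.inf)
    stats: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteome[ids[i]][0], proteome[ids[j]][0]
            alns = aligner.align(a, b)
            if len(alns) == 0:
                continue
            best = alns[0]
            score[i, j] = score[j, i] = float(best.score)
            identity, coverage = _alignment_stats(best, a)
            stats[(i, j)] = (identity, coverage)
    top = np.argmax(score, axis=1)
    candidates = []
    for i in range(n):
        j = int(top[i])
        if score[i, j] == -np.inf:
            continue
        if int(top[j]) == i and i < j:     # reciprocal best hit
            identity, coverage = stats[(i, j)]
            ga, gb = proteome[ids[i]][1], proteome[ids[j]][1]
            if ga.chrom != gb.chrom:
                continue
            if coverage < min_coverage or identity < min_identity:
                continue
            candidates.append((float(score[i, j]), i, j, identity, coverage))
    used: set[int] = set()
    pairs: list[ParalogPair] = []
    for s, i, j, identity, coverage in sorted(candidates, key=lambda t: -t[0]):
        if i in used or j in used:
            continue
        used.update((i, j))
        ga, gb = proteome[ids[i]][1], proteome[ids[j]][1]
        first, second = (ga, gb) if ga.start <= gb.start else (gb, ga)
        pairs.append(ParalogPair(first.gene_id, second.gene_id, ga.chrom,
                                 coverage, identity,
                                 intergenic_distance(ga, gb)))
    pairs.sort(key=lambda p: (p.chrom, p.gene_a))
    return pairs


def linkage_percentile(focal_distance: float,
                       background: list[float] | np.ndarray
                       ) -> dict[str, float]:
    """Empirical percentile of the focal distance among background distances.

    Uses the mid-CDF with mid-ranked ties, clamped to
    [100·0.5/n, 100·(1 − 0.5/n)] so a focal value outside the background's
    range still reports a resolution-limited percentile rather than 0/100
    (same convention as permutation p-values never being 0).
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    n = bg.size
    less = float(np.sum(bg < focal_distance))
    equal = float(np.sum(bg == focal_distance))
    pct = 100.0 * (less + 0.5 * equal) / n
    pct = float(np.clip(pct, 100.0 * 0.5 / n, 100.0 * (1 - 0.5 / n)))
    return {
        "percentile": pct,
        "n_background": int(n),
        "background_median": float(np.median(bg)),
        "background_mean": float(np.mean(bg)),
        "focal_distance": float(focal_distance),
    }
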