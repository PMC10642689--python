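"""Spliced ORF reconstruction by protein-to-genome dynamic programming.

Given a candidate locus, the full query protein is aligned to the genomic
window codon-by-codon: exons are chains of consecutive codons, and between
any two query codons the path may jump through a canonical GT..AG intron of
at least ``min_intron`` nt (phase-0 introns only). The chain maximizing the
summed BLOSUM62 codon-match score minus intron penalties is recovered by
traceback. The model is substitution-only (no in-exon indels), which matches
genes whose divergence from the query is by point substitution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from opsinkit.genome import GeneModel

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_BLOSUM.alphabet)
_AA_INDEX = {c: i for i, c in enumerate(_ALPHA)}
_NEG = -1e8
STOP_CODONS = {"TAA", "TAG", "TGA"}


def _score_table() -> np.ndarray:
    n = len(_ALPHA)
    tab = np.zeros((n, n))
    for i, a in enumerate(_ALPHA):
        for j, b in enumerate(_ALPHA):
            tab[i, j] = _BLOSUM[a][b]
    return tab


_SCORES = _score_table()


def _aa_codes(aa: str) -> np.ndarray:
    x = _AA_INDEX.get("X")
    return np.array([_AA_INDEX.get(c, x) for c in aa], dtype=np.int64)


@dataclass
class SplicedAlignment:
    score: float
    exons: list[tuple[int, int]]   # window-relative, ascending, half-open
    cds: str


def spliced_align(window: str, query: str, intron_penalty: float = 15.0,
                  min_intron: int = 30) -> SplicedAlignment | None:
    """Best full-query spliced alignment of ``query`` into ``window``."""
    m, n = len(query), len(window)
    if n < 3 * m:
        return None
    W = window.upper()
    n_codon_starts = n - 2
    # translated aa at each codon start
    frames = [str(Seq(W[f:f + 3 * ((n - f) // 3)]).translate()) for f in range(3)]
    aa_at = np.empty(n_codon_starts, dtype=np.int64)
    for c in range(n_codon_starts):
        aa_at[c] = _AA_INDEX.get(frames[c % 3][c // 3], _AA_INDEX["X"])
    q_codes = _aa_codes(query.upper())

    is_gt = np.zeros(n + 1, dtype=bool)
    is_ag_end = np.zeros(n + 1, dtype=bool)  # position c where W[c-2:c] == "AG"
    for d in range(n - 1):
        if W[d:d + 2] == "GT":
            is_gt[d] = True
    for c in range(2, n + 1):
        if W[c - 2:c] == "AG":
            is_ag_end[c] = True

    E = np.full((m + 1, n_codon_starts), _NEG)
    # ptr: -2 start, -1 exon continuation, >=0 intron start position d
    ptr = np.full((m + 1, n_codon_starts), -3, dtype=np.int32)

    s_row = _SCORES[q_codes[0]][aa_at]
    E[1] = s_row
    ptr[1] = -2

    cs = np.arange(n_codon_starts)
    for i in range(2, m + 1):
        prev = E[i - 1]
        # exon continuation: previous codon at c-3
        cont = np.full(n_codon_starts, _NEG)
        cont[3:] = prev[:-3]
        # intron arrival: intron [d, c) with W[d:d+2]=GT, W[c-2:c]=AG,
        # c - d >= min_intron; previous codon ended at d (started at d-3)
        # E*(d) = E[i-1][d-3] where W[d:d+2]=GT (intron opens at d)
        ed = np.full(n + 1, _NEG)
        dmax = min(n - 1, n_codon_starts + 2)
        d_idx = np.arange(3, dmax + 1)
        take = d_idx[is_gt[d_idx]]
        if take.size:
            ed[take] = prev[take - 3]
        gmax = np.maximum.accumulate(ed)
        # running argmax: positions achieving the running max, carried forward
        idx = np.arange(n + 1)
        garg = np.maximum.accumulate(np.where(ed == gmax, idx, -1))
        intr = np.full(n_codon_starts, _NEG)
        c_ok = cs[(cs >= min_intron) & is_ag_end[cs]]
        if c_ok.size:
            intr[c_ok] = gmax[c_ok - min_intron] - intron_penalty
        s_row = _SCORES[q_codes[i - 1]][aa_at]
        use_intron = intr > cont
        base = np.where(use_intron, intr, cont)
        E[i] = s_row + base
        ptr[i] = np.where(use_intron, garg[np.clip(cs - min_intron, 0, n)], -1)
        ptr[i][E[i] <= _NEG / 2] = -3

    end_c = int(np.argmax(E[m]))
    score = float(E[m, end_c])
    if score <= _NEG / 2:
        return None

    # traceback
    codon_starts = [0] * m
    c = end_c
    for i in range(m, 0, -1):
        codon_starts[i - 1] = c
        p = int(ptr[i, c])
        if p == -2:
            break
        if p == -1:
            c = c - 3
        else:
            c = p - 3
    exons: list[tuple[int, int]] = []
    for c in codon_starts:
        if exons and c == exons[-1][1]:
            exons[-1] = (exons[-1][0], c + 3)
        else:
            exons.append((c, c + 3))
    cds = "".join(W[a:b] for a, b in exons)
    return SplicedAlignment(score, exons, cds)


def reconstruct_orf(hit, genome: dict[str, str], query: str,
                    flank: int = 3000, min_score: float = 100.0,
                    intron_penalty: float = 15.0, min_intron: int = 30,
                    gene_id: str = "orf") -> GeneModel | None:
    """Build a spliced gene model for a hit/locus; None if no adequate chain.

    ``hit`` needs attributes/keys chrom, strand, and a genomic interval
    (TranslatedHit or a locus dict from :func:`merge_hits_to_loci`).
    """
    if isinstance(hit, dict):
        chrom, strand = hit["chrom"], hit["strand"]
        start, end = hit["start"], hit["end"]
    else:
        chrom, strand = hit.chrom, hit.strand
        start, end = hit.interval
    seq = genome[chrom]
    w0, w1 = max(0, start - flank), min(len(seq), end + flank)
    window = seq[w0:w1]
    if strand == "-":
        window = str(Seq(window).reverse_complement())
    aln = spliced_align(window, query, intron_penalty, min_intron)
    if aln is None or aln.score < min_score:
        return None
    exons = aln.exons
    # terminal stop codon directly after the last matched codon joins the model
    last = exons[-1][1]
    if window[last:last + 3] in STOP_CODONS:
        exons = exons[:-1] + [(exons[-1][0], exons[-1][1] + 3)]
        cds = aln.cds + window[last:last + 3]
    else:
        cds = aln.cds
    if strand == "+":
        g_exons = [(w0 + a, w0 + b) for a, b in exons]
    else:
        Lw = len(window)
        g_exons = sorted((w0 + Lw - b, w0 + Lw - a) for a, b in exons)
    model = GeneModel(gene_id, chrom, strand, g_exons, cds=cds,
                      attributes={"alignment_score": f"{aln.score:.1f}"})
    model.validate()
    return model
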