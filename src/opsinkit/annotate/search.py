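"""Translated homology search: protein query vs genome, six reading frames.

The search emulates a tBLASTn pass at desk scale: exact amino-acid k-mer
seeding (default k = 5) against the six conceptual translations of the
genome, followed by local alignment extension (BLOSUM62, affine gaps) of the
seeded neighborhood. Hits report genomic coordinates (0-based half-open on
the forward strand), percent identity and query coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def make_protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = mode
    return aligner


@dataclass
class TranslatedHit:
    query_id: str
    chrom: str
    strand: str          # '+' or '-'
    interval: tuple[int, int]   # genomic, 0-based half-open, forward strand
    frame: int           # 0..2 within the strand
    score: float
    identity: float      # percent, 0..100
    coverage: float      # aligned query residues / query length

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ValueError("identity out of range")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage out of range")


_SANITIZE_TABLE = {
    i: (chr(i) if chr(i) in str(_BLOSUM62.alphabet) else "X") for i in range(128)
}


def _sanitize(aa: str) -> str:
    # PairwiseAligner rejects letters outside the matrix alphabet
    return aa.translate(_SANITIZE_TABLE)


def _alignment_stats(alignment, query: str):
    qa, ta = alignment[0], alignment[1]
    matches = aligned_cols = q_res = 0
    for a, b in zip(qa, ta):
        if a != "-" and b != "-":
            aligned_cols += 1
            if a == b:
                matches += 1
        if a != "-":
            q_res += 1
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = q_res / len(query) if query else 0.0
    return identity, coverage


def _codon_aa_table() -> np.ndarray:
    from Bio.Data import CodonTable
    std = CodonTable.unambiguous_dna_by_id[1]
    tab = np.full(64, ord("X"), dtype=np.uint8)
    nucs = "ACGT"
    for i, a in enumerate(nucs):
        for j, b in enumerate(nucs):
            for k_, c in enumerate(nucs):
                codon = a + b + c
                aa = std.forward_table.get(codon, "*")
                tab[16 * i + 4 * j + k_] = ord(aa)
    return tab


_CODON_AA = _codon_aa_table()
_NUC_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _NUC_CODE[ord(_c)] = _i
    _NUC_CODE[ord(_c.lower())] = _i


def _fast_translate(seq: str, frame: int) -> str:
    codes = _NUC_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    usable = frame + 3 * ((len(codes) - frame) // 3)
    c = codes[frame:usable].reshape(-1, 3)
    bad = (c == 255).any(axis=1)
    idx = (16 * c[:, 0].astype(np.int32) + 4 * c[:, 1] + c[:, 2]) % 64
    aa = _CODON_AA[idx]
    aa[bad] = ord("X")
    return aa.tobytes().decode()


def six_frame_translations(genome: dict[str, str]):
    """(chrom, strand, frame, translated aa string, chrom length) x 6 frames."""
    out = []
    for chrom, seq in genome.items():
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for frame in range(3):
                out.append((chrom, strand, frame, _fast_translate(s, frame), L))
    return out


def translated_search_multi(queries: dict[str, str], genome: dict[str, str],
                            min_score: float = 60.0, k: int = 5,
                            flank_aa: int = 60, min_seeds: int = 1,
                            frames=None,
                            exclude: list[tuple[str, int, int]] | None = None
                            ) -> list[TranslatedHit]:
    """Search many protein queries against a genome in one six-frame pass.

    ``frames`` may carry a precomputed :func:`six_frame_translations` result
    to amortize translation across annotation rounds; ``min_seeds`` discards
    windows supported by fewer exact k-mer seeds before extension; windows
    falling inside an ``exclude`` interval (chrom, start, end — e.g. loci
    annotated in an earlier round) are skipped without extension. Hits for
    all queries are returned together, sorted by score descending.
    """
    if not genome:
        raise ValueError("empty genome")
    if not queries or any(not q for q in queries.values()):
        raise ValueError("empty query")
    kmer_to_queries: dict[str, list[str]] = {}
    for qid, q in queries.items():
        q = q.upper()
        for i in range(len(q) - k + 1):
            kmer_to_queries.setdefault(q[i:i + k], []).append(qid)
    # integer 5-mer codes for a vectorized genome scan
    code_to_queries: dict[int, list[str]] = {}
    for kmer, qids in kmer_to_queries.items():
        arr = np.frombuffer(kmer.encode(), dtype=np.uint8).astype(np.int64)
        code = 0
        for c in arr:
            code = code * 128 + int(c)
        code_to_queries[code] = qids
    all_codes = np.array(sorted(code_to_queries), dtype=np.int64)
    aligner = make_protein_aligner("local")
    frames = frames or six_frame_translations(genome)
    clean_queries = {qid: _sanitize(q.upper()) for qid, q in queries.items()}
    hits: list[TranslatedHit] = []
    for chrom, strand, frame, aa, L in frames:
        n_aa = len(aa)
        seeds_by_query: dict[str, list[int]] = {}
        if n_aa >= k:
            a = np.frombuffer(aa.encode(), dtype=np.uint8).astype(np.int64)
            codes = np.zeros(n_aa - k + 1, dtype=np.int64)
            for j in range(k):
                codes = codes * 128 + a[j:n_aa - k + 1 + j]
            for i in np.flatnonzero(np.isin(codes, all_codes)):
                for qid in code_to_queries[int(codes[i])]:
                    seeds_by_query.setdefault(qid, []).append(int(i))
        for qid, seed_pos in seeds_by_query.items():
            query = clean_queries[qid]
            windows: list[list[int]] = [[seed_pos[0], seed_pos[0], 1]]
            for p in seed_pos[1:]:
                if p - windows[-1][1] <= len(query):
                    windows[-1][1] = p
                    windows[-1][2] += 1
                else:
                    windows.append([p, p, 1])
            for w0, w1, n_seeds in windows:
                if n_seeds < min_seeds:
                    continue
                a0 = max(0, w0 - flank_aa)
                a1 = min(n_aa, w1 + k + flank_aa)
                if exclude:
                    g0 = frame + 3 * w0
                    g1 = frame + 3 * (w1 + k)
                    if strand == "-":
                        g0, g1 = L - g1, L - g0
                    pad = 500
                    if any(c == chrom and g0 >= s - pad and g1 <= e + pad
                           for c, s, e in exclude):
                        continue
                target = _sanitize(aa[a0:a1])
                score = float(aligner.score(query, target))
                if score < min_score:
                    continue
                best = next(iter(aligner.align(query, target)))
                tseg = best.aligned[1]
                t_start, t_end = a0 + int(tseg[0][0]), a0 + int(tseg[-1][1])
                nt0 = frame + 3 * t_start
                nt1 = frame + 3 * t_end
                interval = (nt0, nt1) if strand == "+" else (L - nt1, L - nt0)
                identity, coverage = _alignment_stats(best, query)
                hits.append(TranslatedHit(qid, chrom, strand, interval,
                                          frame, float(score),
                                          identity, coverage))
    hits.sort(key=lambda h: -h.score)
    return hits


def translated_search(query: str, genome: dict[str, str], min_score: float = 60.0,
                      k: int = 5, query_id: str = "query",
                      flank_aa: int = 60) -> list[TranslatedHit]:
    """Single-query six-frame search; see :func:`translated_search_multi`."""
    return translated_search_multi({query_id: query}, genome,
                                   min_score=min_score, k=k, flank_aa=flank_aa)


def merge_hits_to_loci(hits: list[TranslatedHit], max_gap: int = 1500
                       ) -> list[dict]:
    """Merge hits on the same chromosome and strand into candidate gene loci.

    Multi-exon genes fragment into several frame-local hits; merging within
    ``max_gap`` nt reassembles one locus per gene for ORF reconstruction.
    """
    loci: list[dict] = []
    for h in sorted(hits, key=lambda h: (h.chrom, h.strand, h.interval[0])):
        merged = False
        for loc in loci:
            if (loc["chrom"] == h.chrom and loc["strand"] == h.strand
                    and h.interval[0] <= loc["end"] + max_gap
                    and h.interval[1] >= loc["start"] - max_gap):
                loc["start"] = min(loc["start"], h.interval[0])
                loc["end"] = max(loc["end"], h.interval[1])
                loc["hits"].append(h)
                merged = True
                break
        if not merged:
            loci.append({"chrom": h.chrom, "strand": h.strand,
                         "start": h.interval[0], "end": h.interval[1],
                         "hits": [h]})
    for loc in loci:
        loc["score"] = max(h.score for h in loc["hits"])
        loc["queries"] = sorted({h.query_id for h in loc["hits"]})
    return loci
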