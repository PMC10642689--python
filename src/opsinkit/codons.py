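"""Shared codon machinery: standard genetic code tables and neighbor maps."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]

_std = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_std.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]  # 61 codons
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF = {c: _std.forward_table[c] for c in SENSE_CODONS}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def codon_neighbors(codon: str):
    """All single-nucleotide mutations of a codon (including to stops)."""
    for pos in range(3):
        for nuc in NUCS:
            if nuc != codon[pos]:
                yield pos, codon[:pos] + nuc + codon[pos + 1:]


def translate_codons(indices: np.ndarray) -> str:
    return "".join(AA_OF[SENSE_CODONS[i]] for i in indices)


def cds_to_indices(cds: str) -> np.ndarray:
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    idx = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at nt {i}")
        idx.append(SENSE_INDEX[codon])
    return np.array(idx, dtype=np.int64)


def indices_to_cds(indices: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in indices)
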