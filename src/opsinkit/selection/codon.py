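"""Codon alignments and protein-guided back-translation.

A codon alignment is built from a protein alignment and the corresponding
(unaligned) coding sequences: each amino-acid column becomes its source
codon, each protein gap a triplet gap — the classic PAL2NAL construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from opsinkit.codons import STOP_CODONS


@dataclass
class CodonAlignment:
    sequences: dict[str, str]   # taxon -> aligned codon row (gaps as '---')

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("codon alignment rows differ in length")
        L = lengths.pop() if lengths else 0
        if L % 3:
            raise ValueError("codon alignment length not a multiple of 3")
        self.length_nt = L

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    def row(self, taxon: str) -> str:
        return self.sequences[taxon]


def _translate_cds(cds: str) -> str:
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


def back_translate_alignment(protein_aln: dict[str, str],
                             cds_map: dict[str, str]) -> CodonAlignment:
    """Thread coding sequences through a protein alignment.

    Terminal stop codons on the CDS are tolerated and dropped. A CDS that
    does not translate exactly to its ungapped protein row raises ValueError
    naming the taxon.
    """
    rows: dict[str, str] = {}
    for taxon, prot_row in protein_aln.items():
        if taxon not in cds_map:
            raise ValueError(f"no CDS for taxon {taxon!r}")
        cds = cds_map[taxon].upper()
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = prot_row.replace("-", "").replace(".", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"taxon {taxon!r}: CDS length {len(cds)} != 3 x protein "
                f"length {len(ungapped)}")
        if _translate_cds(cds) != ungapped.upper():
            raise ValueError(f"taxon {taxon!r}: CDS does not translate to "
                             f"its protein row")
        out, k = [], 0
        for ch in prot_row:
            if ch in "-.":
                out.append("---")
            else:
                out.append(cds[3 * k:3 * k + 3])
                k += 1
        rows[taxon] = "".join(out)
    return CodonAlignment(rows)
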