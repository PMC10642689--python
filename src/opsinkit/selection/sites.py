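"""Spectral-tuning-site reporting in reference coordinates.

Known tuning sites (e.g. the blue-opsin S116A substitution behind 5–13 nm
shifts in peak absorbance, or G175S/Y177F) are given as 1-based positions in
an ungapped reference sequence; every other taxon's residue at the aligned
column is reported as a substitution label like "S116A", or "missing" when
the taxon has a gap there.
"""

from __future__ import annotations


def tuning_site_report(protein_aln: dict[str, str], reference_id: str,
                       sites: list[int]) -> list[dict]:
    """Report residues at reference-numbered sites for all non-reference taxa.

    Returns one record per (site, taxon) with keys: site, reference_residue,
    taxon, residue, label ("S116A"-style; "" when identical; "missing" for a
    gap). Raises ValueError for a missing reference or out-of-range site.
    """
    if reference_id not in protein_aln:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref_row = protein_aln[reference_id]
    # map 1-based ungapped reference position -> alignment column
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch not in "-.":
            pos += 1
            col_of[pos] = col
    ref_len = pos
    records: list[dict] = []
    for site in sites:
        if not 1 <= site <= ref_len:
            raise ValueError(f"site {site} beyond reference length {ref_len}")
        col = col_of[site]
        ref_res = ref_row[col]
        for taxon in sorted(protein_aln):
            if taxon == reference_id:
                continue
            res = protein_aln[taxon][col]
            if res in "-.":
                label = "missing"
            elif res == ref_res:
                label = ""
            else:
                label = f"{ref_res}{site}{res}"
            records.append({
                "site": site,
                "reference_residue": ref_res,
                "taxon": taxon,
                "residue": res,
                "label": label,
            })
    return records
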