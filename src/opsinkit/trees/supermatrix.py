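"""Species-tree estimation from concatenated per-gene protein alignments.

Each ortholog set contributes its aligned columns to a per-species
supermatrix row; species missing a gene receive a gap block of that gene's
alignment length. Pairwise distances are computed over ungapped columns
only, the topology comes from neighbor joining, and the tree is rooted by a
declared outgroup when given, else at the midpoint.
"""

from __future__ import annotations

import dendropy

from opsinkit.trees.distance import distance_matrix_from_alignment
from opsinkit.trees.nj import build_nj_tree, root_tree


def concatenate_supermatrix(ortholog_sets: list[dict[str, str]],
                            gap_fill: bool = True) -> dict[str, str]:
    """Concatenate aligned ortholog sets into per-species rows."""
    if not ortholog_sets:
        raise ValueError("no ortholog sets supplied")
    all_species = sorted(set().union(*(set(s) for s in ortholog_sets)))
    if not gap_fill:
        shared = set(all_species)
        for s in ortholog_sets:
            shared &= set(s)
        if not shared:
            raise ValueError("no species shared across all sets and gap "
                             "filling is disallowed")
        all_species = sorted(shared)
    rows = {sp: [] for sp in all_species}
    for gene in ortholog_sets:
        lengths = {len(s) for s in gene.values()}
        if len(lengths) != 1:
            raise ValueError("ortholog set rows are not aligned (unequal length)")
        L = lengths.pop()
        for sp in all_species:
            rows[sp].append(gene.get(sp, "-" * L))
    return {sp: "".join(parts) for sp, parts in rows.items()}


def build_supermatrix_species_tree(ortholog_sets: list[dict[str, str]],
                                   outgroup: list[str] | None = None,
                                   gap_fill: bool = True) -> dendropy.Tree:
    """Concatenate, compute distances, NJ, then root (outgroup or midpoint)."""
    matrix = concatenate_supermatrix(ortholog_sets, gap_fill=gap_fill)
    if len(matrix) < 3:
        raise ValueError("supermatrix needs at least 3 species")
    dm = distance_matrix_from_alignment(matrix)
    nj = build_nj_tree(dm)
    if outgroup:
        return root_tree(nj, "outgroup", outgroup_ids=outgroup)
    return root_tree(nj, "midpoint")
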