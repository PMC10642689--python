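"""Neighbor-joining tree construction and rooting utilities.

Standard Saitou–Nei NJ with the common negative-branch-length fix: a negative
pendant length is clamped to zero and the deficit moved to its sibling so the
pair's summed path length is preserved. Trees are dendropy objects; the NJ
result is unrooted (trifurcating seed node).
"""

from __future__ import annotations

import warnings

import numpy as np
import dendropy

from opsinkit.trees.distance import DistanceMatrix


def build_nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining; requires >= 3 taxa; returns an unrooted tree."""
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    frags = [f"{lab}" for lab in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:        # clamp, move deficit to the sibling branch
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        new_frag = f"({frags[i]}:{li:.10f},{frags[j]}:{lj:.10f})"
        # distances to the new node
        for m_loc, m in enumerate(active):
            if m in (i, j):
                continue
            d[i, m] = d[m, i] = max(0.0, 0.5 * (d[i, m] + d[j, m] - dij))
        frags[i] = new_frag
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    newick = f"({frags[a]}:{la:.10f},{frags[b]}:{lb:.10f},{frags[c]}:{lc:.10f});"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _leaf_labels(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def root_tree(tree: dendropy.Tree, method: str = "midpoint",
              outgroup_ids: list[str] | None = None) -> dendropy.Tree:
    """Root an (unrooted) tree by midpoint or by outgroup.

    Outgroup rooting splits the branch subtending the outgroup's LCA in half.
    A non-monophyletic outgroup (in the unrooted sense) produces a warning
    and a minimal-conflict root at the LCA edge of the outgroup leaves; the
    conflict is recorded in ``tree.annotations``.
    """
    t = tree.clone(depth=1)
    t.is_rooted = True
    if method == "midpoint":
        t.reroot_at_midpoint(update_bipartitions=True,
                             suppress_unifurcations=True)
        return t
    if method != "outgroup":
        raise ValueError(f"unknown rooting method {method!r}")
    if not outgroup_ids:
        raise ValueError("outgroup rooting requires outgroup_ids")
    og = set(outgroup_ids)
    all_leaves = _leaf_labels(t.seed_node)
    if not og <= all_leaves:
        raise ValueError("outgroup ids absent from tree")
    mrca = t.mrca(taxon_labels=sorted(og))
    clade = _leaf_labels(mrca)
    monophyletic = clade == og
    if not monophyletic:
        # unrooted monophyly also holds if the complement is a clade
        comp = all_leaves - og
        comp_mrca = t.mrca(taxon_labels=sorted(comp)) if comp else None
        if comp_mrca is not None and _leaf_labels(comp_mrca) == comp:
            mrca = comp_mrca
            monophyletic = True
    if not monophyletic:
        warnings.warn("outgroup not monophyletic; using minimal-conflict root")
        t.annotations.add_new("outgroup_conflict", "true")
    if mrca is t.seed_node:
        # outgroup spans the seed; root on the first outgroup leaf's edge
        mrca = next(lf for lf in t.leaf_node_iter()
                    if lf.taxon.label in og)
    edge = mrca.edge
    half = (edge.length or 0.0) / 2.0
    t.reroot_at_edge(edge, length1=half, length2=half,
                     update_bipartitions=True, suppress_unifurcations=True)
    return t
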