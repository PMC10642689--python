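"""Clade ω-ratio permutation test — a proxy for selection-intensity shifts.

The foreground ω is the mean pairwise NG86 ω among foreground sequences;
likewise for the background. Their ratio R = ω_fg / ω_bg exceeding 1 signals
elevated foreground ω, which, when the background is under purifying
selection (ω_bg < 1), is the signature of relaxed selection on the
foreground clade. Significance comes from permuting the leaf-to-partition
assignment; this is an explicitly labelled proxy for likelihood-based
selection-intensity parameters (e.g. RELAX's k), not a reimplementation of
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from opsinkit.selection.ng86 import pairwise_omega_matrix


@dataclass
class RelaxationResult:
    omega_foreground: float
    omega_background: float
    ratio: float          # R = ω_fg / ω_bg; R > 1 -> elevated foreground ω
    p_value: float        # one-sided, for R > 1
    n_permutations: int
    seed: int


def _mean_within(om: np.ndarray, idx: np.ndarray) -> float:
    sub = om[np.ix_(idx, idx)]
    vals = sub[np.triu_indices(len(idx), k=1)]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def relaxation_test(codon_aln: dict[str, str], foreground_ids: list[str],
                    n_perm: int = 999, seed: int = 0,
                    gene_tree=None) -> RelaxationResult:
    """Permutation test of elevated mean pairwise ω in a foreground clade.

    ``foreground_ids`` must be a proper, non-empty subset of the alignment's
    taxa with >= 2 members on each side. When a gene tree is supplied the
    foreground must form a clade in it (sanity check only).
    """
    ids = sorted(codon_aln)
    fg = sorted(set(foreground_ids))
    bg = [i for i in ids if i not in set(fg)]
    if not set(fg) <= set(ids):
        raise ValueError("foreground ids absent from alignment")
    if len(fg) < 2 or len(bg) < 2:
        raise ValueError("need >= 2 leaves on each side of the partition")
    if gene_tree is not None:
        mrca = gene_tree.mrca(taxon_labels=fg)
        clade = {lf.taxon.label for lf in mrca.leaf_iter()}
        if clade != set(fg):
            raise ValueError("foreground is not a clade in the gene tree")

    mat_ids, om = pairwise_omega_matrix(codon_aln)
    pos = {t: i for i, t in enumerate(mat_ids)}
    fg_idx = np.array([pos[t] for t in fg])
    bg_idx = np.array([pos[t] for t in bg])

    w_fg = _mean_within(om, fg_idx)
    w_bg = _mean_within(om, bg_idx)
    ratio = w_fg / w_bg if w_bg > 0 else float("inf")

    rng = np.random.default_rng(seed)
    n = len(mat_ids)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pf, pb = perm[:len(fg)], perm[len(fg):]
        rf = _mean_within(om, pf)
        rb = _mean_within(om, pb)
        r = rf / rb if rb > 0 else float("inf")
        if r >= ratio - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return RelaxationResult(w_fg, w_bg, float(ratio), float(p), n_perm, seed)
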