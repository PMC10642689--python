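"""Codon sequence evolution under an HKY-style process with an ω multiplier.

Each codon evolves independently by a continuous-time Markov chain on the 61
sense codons. A single-nucleotide change has rate proportional to κ for
transitions (1 for transversions), multiplied by ω when the change is
nonsynonymous; changes creating a stop codon have rate 0, so no internal stop
can ever arise. Rates are normalized so that one unit of branch length equals
one expected substitution per nucleotide site under neutrality (ω = 1), i.e.
branch lengths are in neutral substitutions/site.

This is a simplified analogue of the MG94 codon model: the ω semantics (the
nonsynonymous/synonymous rate ratio) are identical, which is what the
downstream dN/dS estimator measures.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from opsinkit.codons import (
    SENSE_CODONS,
    SENSE_INDEX,
    AA_OF,
    STOP_CODONS,
    codon_neighbors,
    is_transition,
    cds_to_indices,
    indices_to_cds,
)
from opsinkit.simul.history import EventLedger, GNode

_MAX_NBR = 9


@lru_cache(maxsize=64)
def _rate_tables(kappa: float, omega: float):
    """Per-codon total leave rates, neighbor indices and cumulative probs."""
    n = len(SENSE_CODONS)
    total = np.zeros(n)
    nbr_idx = np.full((n, _MAX_NBR), -1, dtype=np.int64)
    nbr_cum = np.zeros((n, _MAX_NBR))
    scale = 1.0 / (kappa + 2.0)  # neutral rate 1 per nucleotide site
    for i, codon in enumerate(SENSE_CODONS):
        rates, targets = [], []
        for pos, other in codon_neighbors(codon):
            if other in STOP_CODONS:
                continue
            r = (kappa if is_transition(codon[pos], other[pos]) else 1.0) * scale
            if AA_OF[other] != AA_OF[codon]:
                r *= omega
            if r > 0:
                rates.append(r)
                targets.append(SENSE_INDEX[other])
        total[i] = sum(rates)
        if rates:
            nbr_idx[i, :len(targets)] = targets
            nbr_cum[i, :len(rates)] = np.cumsum(rates) / total[i]
            nbr_cum[i, len(rates):] = 1.0
    return total, nbr_idx, nbr_cum


def evolve_branch(seq: np.ndarray, t: float, omega: float, kappa: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Evolve codon indices for branch length t (neutral substitutions/site)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    seq = seq.copy()
    if t == 0 or len(seq) == 0:
        return seq
    total, nbr_idx, nbr_cum = _rate_tables(float(kappa), float(omega))
    remaining = np.full(len(seq), float(t))
    active = np.arange(len(seq))
    while active.size:
        rates = total[seq[active]]
        waits = rng.exponential(1.0, size=active.size) / np.maximum(rates, 1e-300)
        waits[rates <= 0] = np.inf
        remaining[active] -= waits
        hit = active[remaining[active] > 0]
        if hit.size:
            u = rng.random(hit.size)
            choice = (nbr_cum[seq[hit]] < u[:, None]).sum(axis=1)
            seq[hit] = nbr_idx[seq[hit], choice]
        active = hit
    return seq


def random_root_cds(n_codons: int, rng: np.random.Generator,
                    start_codon: bool = True) -> str:
    """Uniform random sense codons; first codon ATG when start_codon."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    cds = indices_to_cds(idx)
    if start_codon:
        cds = "ATG" + cds[3:]
    return cds


def simulate_codon_pair(n_codons: int, t: float, omega: float, kappa: float,
                        seed: int) -> tuple[str, str]:
    """Two sequences diverged by total branch length t under (κ, ω)."""
    rng = np.random.default_rng(seed)
    root = cds_to_indices(random_root_cds(n_codons, rng, start_codon=False))
    a = evolve_branch(root, t / 2, omega, kappa, rng)
    b = evolve_branch(root, t / 2, omega, kappa, rng)
    return indices_to_cds(a), indices_to_cds(b)


def evolve_codon_sequences(ledger: EventLedger, tree=None, cfg=None,
                           root_cds_map: dict[str, str] | None = None
                           ) -> dict[str, str]:
    """Evolve one CDS per extant gene down the true gene genealogies.

    Returns gene_id -> coding sequence (without the terminal stop codon, which
    the genome emitter appends). Also stores each family's ancestral CDS under
    the key ``__root__<family>``. Deterministic given ``cfg.seed``. Ancestral
    sequences may be supplied via ``root_cds_map`` (family -> CDS); they must
    be stop-free and a multiple of 3 long, else ValueError.
    """
    cfg = cfg or ledger.cfg
    out: dict[str, str] = {}
    for k, (fam, root) in enumerate(sorted(ledger.roots.items())):
        rng = np.random.default_rng([cfg.seed % (2**31), 7, k])
        if root_cds_map is not None and fam in root_cds_map:
            root_cds = root_cds_map[fam]
            cds_to_indices(root_cds)  # validates length and stop-freedom
        else:
            root_cds = random_root_cds(cfg.n_codons, rng)
        out[f"__root__{fam}"] = root_cds

        def walk(gn: GNode, seq: np.ndarray) -> None:
            seq = evolve_branch(seq, gn.length * cfg.rate_scale, gn.omega,
                                cfg.kappa, rng)
            if gn.gene_id is not None:
                out[gn.gene_id] = indices_to_cds(seq)
            for child in gn.children:
                walk(child, seq)

        walk(root, cds_to_indices(root_cds))
    return out
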