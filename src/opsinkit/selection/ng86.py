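"""Nei–Gojobori (1986) counting estimator of dN/dS.

Synonymous site counts: at each codon position the synonymous fraction is
the number of synonymous single-nucleotide changes divided by the number of
possible changes, with mutations creating a stop codon excluded from the
possible-change set. Differences between two codons are averaged over all
shortest mutational pathways (k! orderings for k differing positions),
discarding pathways that pass through a stop codon; in the degenerate case
where every pathway passes through a stop, all pathways are used.
Proportions are Jukes–Cantor corrected: d = −(3/4)·ln(1 − (4/3)p).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from opsinkit.codons import AA_OF, NUCS, SENSE_CODONS, SENSE_INDEX, STOP_CODONS

SATURATION_P = 0.74  # pS or pN at/above this is flagged saturated


class UndefinedResultError(ValueError):
    """No comparable codon columns between the two rows."""


@dataclass
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float          # nan when undefined, inf when dS == 0 < dN
    n_codons: int
    flags: dict = field(default_factory=dict)


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3)."""
    total = 0.0
    for pos in range(3):
        syn = possible = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            other = codon[:pos] + nuc + codon[pos + 1:]
            if other in STOP_CODONS:
                continue
            possible += 1
            if AA_OF[other] == AA_OF[codon]:
                syn += 1
        if possible:
            total += syn / possible
    return total


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk_path(order):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                nonsyn += 1   # stop-passing fallback treats the step nonsyn
            else:
                if AA_OF.get(nxt) == AA_OF.get(cur, object()):
                    syn += 1
                else:
                    nonsyn += 1
            cur = nxt
        return syn, nonsyn, through_stop

    clean, dirty = [], []
    for order in itertools.permutations(diff_pos):
        syn, nonsyn, through_stop = walk_path(order)
        (dirty if through_stop else clean).append((syn, nonsyn))
    paths = clean if clean else dirty
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; nan when p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def _comparable_codons(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("codon rows must have equal length")
    if len(a) % 3:
        raise ValueError("row length not a multiple of 3")
    for k in range(0, len(a), 3):
        ca, cb = a[k:k + 3].upper(), b[k:k + 3].upper()
        if ca in SENSE_INDEX and cb in SENSE_INDEX:
            yield ca, cb


def ng86_dnds(a: str, b: str) -> DnDsResult:
    """NG86 dN/dS between two equal-length codon rows.

    Columns containing a gap, ambiguity or stop codon in either row are
    skipped. Raises UndefinedResultError when nothing is comparable.
    """
    S = N = Sd = Nd = 0.0
    n = 0
    for ca, cb in _comparable_codons(a, b):
        n += 1
        S += 0.5 * (_syn_sites(ca) + _syn_sites(cb))
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    if n == 0:
        raise UndefinedResultError("no comparable codons")
    N = 3.0 * n - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    flags = {
        "dS_zero": Sd == 0.0,
        "saturated": (pS >= SATURATION_P) or (pN >= SATURATION_P),
    }
    if np.isnan(dS) or np.isnan(dN):
        flags["saturated"] = True
        omega = float("nan")
    elif dS == 0.0:
        omega = float("inf") if dN > 0 else float("nan")
    else:
        omega = dN / dS
    return DnDsResult(S, N, Sd, Nd, pS, pN,
                      float(dS), float(dN), float(omega), n, flags)


def pairwise_omega_matrix(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """All-pairs NG86 ω; nan where undefined/saturated. Symmetric."""
    ids = sorted(rows)
    n = len(ids)
    om = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = ng86_dnds(rows[ids[i]], rows[ids[j]])
            except UndefinedResultError:
                continue
            if not res.flags["saturated"] and np.isfinite(res.omega):
                om[i, j] = om[j, i] = res.omega
    return ids, om
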