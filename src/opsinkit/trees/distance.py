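"""Protein distances and the distance-matrix container.

Distances use the Kimura protein correction of the observed proportion of
differing ungapped columns p:

    d = -ln(1 - p - 0.2 p^2)

capped at a configurable maximum when the logarithm's argument is
non-positive (p >= ~0.8541).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MAX_DISTANCE = 10.0


class UndefinedDistanceError(ValueError):
    """No ungapped overlap between two aligned sequences."""


def pairwise_protein_distance(a: str, b: str,
                              max_distance: float = DEFAULT_MAX_DISTANCE) -> float:
    """Kimura-corrected distance between two aligned protein sequences."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    n = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        n += 1
        if x != y:
            diff += 1
    if n == 0:
        raise UndefinedDistanceError("zero ungapped overlap")
    p = diff / n
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return max_distance
    return min(-np.log(arg), max_distance)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix_from_alignment(seqs: dict[str, str],
                                   max_distance: float = DEFAULT_MAX_DISTANCE
                                   ) -> DistanceMatrix:
    ids = sorted(seqs)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_protein_distance(seqs[ids[i]], seqs[ids[j]],
                                          max_distance=max_distance)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)


def jc_nucleotide_distance(a: str, b: str,
                           max_distance: float = DEFAULT_MAX_DISTANCE) -> float:
    """Jukes–Cantor nucleotide distance over ungapped columns.

    d = −(3/4)·ln(1 − (4/3)p); capped at ``max_distance`` when p >= 3/4.
    Gene trees benefit from nucleotide distances because under purifying
    selection most substitutions are synonymous and invisible to protein
    distances.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    n = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-." or x == "N" or y == "N":
            continue
        n += 1
        if x != y:
            diff += 1
    if n == 0:
        raise UndefinedDistanceError("zero ungapped overlap")
    p = diff / n
    if p >= 0.75:
        return max_distance
    return min(-0.75 * np.log(1.0 - (4.0 / 3.0) * p), max_distance)


def distance_matrix_from_cds(seqs: dict[str, str],
                             max_distance: float = DEFAULT_MAX_DISTANCE
                             ) -> DistanceMatrix:
    ids = sorted(seqs)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc_nucleotide_distance(seqs[ids[i]], seqs[ids[j]],
                                       max_distance=max_distance)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)
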