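"""Rank-based comparison of per-species ω between diel-niche groups.

The statistic is Kruskal–Wallis H across the groups (nocturnal / diurnal /
both, or any >= 2 groups); significance comes from a label-permutation null,
so no chi-square approximation is invoked at small n. Non-finite ω values
(undefined or saturated estimates) are excluded up front and their count
reported.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def compare_groups_dnds(values: dict[str, list[float] | np.ndarray],
                        n_perm: int = 1999, seed: int = 0) -> dict:
    """Permutation Kruskal–Wallis test of ω values across groups.

    Returns dict with statistic, p_value (= (b+1)/(n_perm+1)), group sizes
    and the number of excluded non-finite values. Raises ValueError when any
    group has fewer than 2 finite values.
    """
    groups: list[np.ndarray] = []
    labels: list[str] = []
    n_excluded = 0
    for lab in sorted(values):
        arr = np.asarray(values[lab], dtype=float)
        finite = arr[np.isfinite(arr)]
        n_excluded += arr.size - finite.size
        if finite.size < 2:
            raise ValueError(f"group {lab!r} has <2 finite values")
        groups.append(finite)
        labels.append(lab)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    tie_correction = _tie_correction(ranks, n)
    cuts = np.cumsum(sizes)[:-1]

    def h_from_ranks(r: np.ndarray) -> float:
        parts = np.split(r, cuts)
        h = 12.0 / (n * (n + 1)) * sum(p.sum() ** 2 / p.size for p in parts) \
            - 3.0 * (n + 1)
        return h / tie_correction if tie_correction > 0 else 0.0

    obs_h = h_from_ranks(ranks)
    b = 0
    for _ in range(n_perm):
        if h_from_ranks(rng.permutation(ranks)) >= obs_h - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return {
        "statistic": float(obs_h),
        "p_value": float(p),
        "n_perm": n_perm,
        "groups": dict(zip(labels, sizes)),
        "n_excluded": int(n_excluded),
    }


def _tie_correction(ranks: np.ndarray, n: int) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
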