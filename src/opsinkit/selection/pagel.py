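"""Correlated evolution of two binary traits on a phylogeny (Mk models).

Tests whether opsin-duplication presence and diel niche evolved
independently: the null model evolves each binary trait under its own
2-state Markov chain (4 rates total); the alternative evolves the joint
4-state system (00, 01, 10, 11) with 8 single-trait transition rates whose
values may depend on the other trait's state. Likelihoods are computed by
Felsenstein pruning with uniform root frequencies; the likelihood-ratio
statistic LR = 2(lnL_dep − lnL_indep) is calibrated by parametric bootstrap
under the fitted independent model, so no chi-square approximation is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

_LOG_RATE_BOUNDS = (-8.0, 4.0)


@dataclass
class TraitVector:
    """Binary states for each species: diel niche and duplication presence.

    ``diel`` maps species -> {"nocturnal", "diurnal", "both"}; ``duplicated``
    maps species -> {0, 1}. Species labelled "both" are excluded from the
    binary test by default, or merged into "diurnal" when merge_both is set.
    """

    diel: dict[str, str]
    duplicated: dict[str, int]

    def binary(self, merge_both: bool = False) -> tuple[dict[str, int], dict[str, int], list[str]]:
        a, b, excluded = {}, {}, []
        for sp, st in self.diel.items():
            if st == "both" and not merge_both:
                excluded.append(sp)
                continue
            a[sp] = 1 if st in ("diurnal", "both") else 0
            b[sp] = int(self.duplicated[sp])
        return a, b, excluded


class _TreeArrays:
    """Flat postorder arrays for fast repeated pruning (binary trees)."""

    def __init__(self, tree, taxa: list[str]):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[tuple[int, ...]] = []
        self.branch_lengths = np.zeros(self.n_nodes)
        self.leaf_index: dict[str, int] = {}
        taxa_set = set(taxa)
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            self.children.append(tuple(index[id(k)] for k in kids))
            self.branch_lengths[i] = nd.edge.length or 0.0
            if not kids:
                lab = nd.taxon.label
                if lab in taxa_set:
                    self.leaf_index[lab] = i
            elif len(kids) != 2:
                raise ValueError("trait models require a binary tree")
        missing = taxa_set - set(self.leaf_index)
        if missing:
            raise ValueError(f"species missing from tree: {sorted(missing)}")
        self.root = self.n_nodes - 1
        self.internal = [i for i, c in enumerate(self.children) if c]
        self.c1 = np.array([c[0] for i, c in enumerate(self.children) if c])
        self.c2 = np.array([c[1] for i, c in enumerate(self.children) if c])
        # mean root-to-tip depth, for the rate identifiability cap
        depth = np.zeros(self.n_nodes)
        for i in reversed(range(self.n_nodes)):
            for c in self.children[i]:
                depth[c] = depth[i] + self.branch_lengths[c]
        tips = [i for i, c in enumerate(self.children) if not c]
        self.height = float(np.mean(depth[tips])) if tips else 1.0

    def rate_bounds(self) -> tuple[float, float]:
        """Log-rate box: above ~10 expected changes root-to-tip, rates are
        unidentifiable and only destabilize the parametric bootstrap."""
        hi = float(np.log(max(10.0 / max(self.height, 1e-9), 1.0)))
        return (_LOG_RATE_BOUNDS[0], max(hi, _LOG_RATE_BOUNDS[0] + 2.0))


def _p2(q01: float, q10: float, t: np.ndarray) -> np.ndarray:
    """Closed-form 2-state transition matrices for all branch lengths."""
    s = q01 + q10
    e = np.exp(-s * t)
    pi0, pi1 = (q10 / s, q01 / s) if s > 0 else (0.5, 0.5)
    P = np.empty((t.size, 2, 2))
    P[:, 0, 0] = pi0 + pi1 * e
    P[:, 0, 1] = pi1 * (1 - e)
    P[:, 1, 0] = pi0 * (1 - e)
    P[:, 1, 1] = pi1 + pi0 * e
    return P


def _pk(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Transition matrices exp(Q t) for all branches via eigendecomposition."""
    lam, V = np.linalg.eig(Q)
    Vinv = np.linalg.inv(V)
    E = np.exp(np.outer(t, lam))                      # (B, k)
    P = np.einsum("ik,bk,kj->bij", V, E, Vinv).real
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _prune(ta: _TreeArrays, P: np.ndarray, leaf_states: dict[str, int],
           k: int) -> float:
    """Felsenstein pruning with uniform root frequencies.

    Conditional likelihoods are left unnormalized (safe in double precision
    for the tree sizes used here; see _TreeArrays).
    """
    L = np.ones((ta.n_nodes, k))
    for lab, i in ta.leaf_index.items():
        L[i] = 0.0
        L[i, leaf_states[lab]] = 1.0
    internal = ta.internal
    c1, c2 = ta.c1, ta.c2
    for j in range(len(internal)):
        i = internal[j]
        a, b = c1[j], c2[j]
        L[i] = (P[a] @ L[a]) * (P[b] @ L[b])
    root_like = L[ta.root].mean()
    if root_like <= 0:
        return -np.inf
    return float(np.log(root_like))


def _fit_single_trait(ta: _TreeArrays, states: dict[str, int]) -> tuple[float, tuple[float, float]]:
    t = ta.branch_lengths

    def nll(x):
        q01, q10 = np.exp(x)
        return -_prune(ta, _p2(q01, q10, t), states, 2)

    height = max(t.sum() / max(1, len(ta.leaf_index)), 1e-6)
    x0 = np.log([1.0 / height, 1.0 / height])
    best = None
    for scale in (1.0, 0.2, 5.0):
        res = minimize(nll, x0 + np.log(scale), method="L-BFGS-B",
                       bounds=[ta.rate_bounds()] * 2,
                       options={"maxiter": 100})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, tuple(np.exp(best.x))


def _dependent_Q(rates: np.ndarray) -> np.ndarray:
    """8-rate joint matrix on states (00, 01, 10, 11), single-trait moves only.

    Order: qB(0->1)|A=0, qB(1->0)|A=0, qB(0->1)|A=1, qB(1->0)|A=1,
           qA(0->1)|B=0, qA(1->0)|B=0, qA(0->1)|B=1, qA(1->0)|B=1.
    """
    b01_a0, b10_a0, b01_a1, b10_a1, a01_b0, a10_b0, a01_b1, a10_b1 = rates
    Q = np.zeros((4, 4))
    # states indexed 0:(A0,B0) 1:(A0,B1) 2:(A1,B0) 3:(A1,B1)
    Q[0, 1], Q[1, 0] = b01_a0, b10_a0
    Q[2, 3], Q[3, 2] = b01_a1, b10_a1
    Q[0, 2], Q[2, 0] = a01_b0, a10_b0
    Q[1, 3], Q[3, 1] = a01_b1, a10_b1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _fit_dependent(ta: _TreeArrays, joint_states: dict[str, int],
                   init_rates: np.ndarray, thorough: bool = True) -> float:
    t = ta.branch_lengths

    def nll(x):
        Q = _dependent_Q(np.exp(x))
        with np.errstate(all="ignore"):
            try:
                P = _pk(Q, t)
            except np.linalg.LinAlgError:
                return 1e10
        if not np.all(np.isfinite(P)):
            return 1e10
        return -_prune(ta, P, joint_states, 4)

    x0 = np.log(np.clip(init_rates, 1e-3, None))
    starts = (x0, x0 + np.log(0.3), x0 + np.log(3.0)) if thorough else (x0,)
    best = None
    for x_start in starts:
        res = minimize(nll, x_start, method="L-BFGS-B",
                       bounds=[ta.rate_bounds()] * 8,
                       options={"maxiter": 60 if thorough else 25,
                                "gtol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


def _simulate_trait(ta: _TreeArrays, q01: float, q10: float,
                    rng: np.random.Generator) -> dict[str, int]:
    t = ta.branch_lengths
    P = _p2(q01, q10, t)
    states = np.zeros(ta.n_nodes, dtype=int)
    order = list(range(ta.n_nodes))[::-1]              # preorder (reverse postorder)
    states[ta.root] = rng.integers(2)
    for i in order:
        for c in ta.children[i]:
            states[c] = rng.choice(2, p=P[c, states[i]])
    return {lab: int(states[i]) for lab, i in ta.leaf_index.items()}


def trait_association_test(tree, traits: TraitVector, n_boot: int = 199,
                           seed: int = 0, merge_both: bool = False) -> dict:
    """LR test of correlated evolution with parametric-bootstrap p-value.

    Returns dict with lr, p_value, lnL_indep, lnL_dep, n_excluded and the
    fitted independent-model rates. An invariant trait short-circuits to
    LR = 0, p = 1 with a warning (no information about correlation).
    """
    a, b, excluded = traits.binary(merge_both=merge_both)
    taxa = sorted(a)
    ta = _TreeArrays(tree, taxa)
    if len(set(a.values())) < 2 or len(set(b.values())) < 2:
        warnings.warn("invariant trait: association test degenerate")
        return {"lr": 0.0, "p_value": 1.0, "lnL_indep": np.nan,
                "lnL_dep": np.nan, "n_excluded": len(excluded),
                "degenerate": True}

    def lr_for(sa: dict[str, int], sb: dict[str, int], thorough=True
               ) -> tuple[float, float, float, np.ndarray]:
        lnl_a, (qa01, qa10) = _fit_single_trait(ta, sa)
        lnl_b, (qb01, qb10) = _fit_single_trait(ta, sb)
        lnl_indep = lnl_a + lnl_b
        joint = {sp: 2 * sa[sp] + sb[sp] for sp in sa}
        init = np.array([qb01, qb10, qb01, qb10, qa01, qa10, qa01, qa10])
        lnl_dep = _fit_dependent(ta, joint, init, thorough=thorough)
        lr = max(0.0, 2.0 * (lnl_dep - lnl_indep))
        return lr, lnl_indep, lnl_dep, np.array([qa01, qa10, qb01, qb10])

    # the observed statistic uses the same single-start fitting protocol as
    # the bootstrap replicates, keeping the two exchangeable
    lr_obs, lnl_indep, lnl_dep, rates = lr_for(a, b, thorough=False)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sa = _simulate_trait(ta, rates[0], rates[1], rng)
        sb = _simulate_trait(ta, rates[2], rates[3], rng)
        if len(set(sa.values())) < 2 or len(set(sb.values())) < 2:
            lr_b = 0.0
        else:
            lr_b = lr_for(sa, sb, thorough=False)[0]
        if lr_b >= lr_obs - 1e-9:
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    return {"lr": float(lr_obs), "p_value": float(p),
            "lnL_indep": float(lnl_indep), "lnL_dep": float(lnl_dep),
            "n_excluded": len(excluded), "n_boot": n_boot,
            "independent_rates": rates.tolist(), "degenerate": False}
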