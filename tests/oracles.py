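"""Independent brute-force oracles used only by the test suite.

These re-derive quantities from first principles with deliberately naive
code (explicit enumeration, recursion, sorting) so they share no code path
with the library implementations they check.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


def _aa(codon):
    return _TABLE.forward_table.get(codon)


def ng86_sites_oracle(codon: str) -> float:
    """Synonymous site count of one codon by explicit enumeration."""
    total = 0.0
    for pos in range(3):
        syn, denom = 0, 0
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1:]
            if mut in _STOPS:
                continue
            denom += 1
            if _aa(mut) == _aa(codon):
                syn += 1
        if denom:
            total += syn / denom
    return total


def ng86_path_oracle(c1: str, c2: str):
    """(Sd, Nd) averaged over stop-avoiding shortest paths, by recursion."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]

    def paths(cur, remaining):
        if not remaining:
            yield []
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            for rest in paths(nxt, [p for p in remaining if p != pos]):
                yield [(cur, nxt)] + rest

    def score(path):
        syn = nonsyn = 0
        stop = False
        for a, b in path:
            if b in _STOPS or a in _STOPS:
                stop = True
                nonsyn += 1
            elif _aa(a) == _aa(b):
                syn += 1
            else:
                nonsyn += 1
        return syn, nonsyn, stop

    all_paths = [score(p) for p in paths(c1, diffs)]
    clean = [(s, n) for s, n, stop in all_paths if not stop]
    use = clean if clean else [(s, n) for s, n, _ in all_paths]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def ng86_pair_oracle(row_a: str, row_b: str):
    """Full NG86 (S, N, Sd, Nd, dS, dN) for two codon rows, naive version."""
    import math
    S = Sd = Nd = 0.0
    n = 0
    for k in range(0, len(row_a), 3):
        ca, cb = row_a[k:k + 3], row_b[k:k + 3]
        if ca in _STOPS or cb in _STOPS:
            continue
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue
        n += 1
        S += (ng86_sites_oracle(ca) + ng86_sites_oracle(cb)) / 2
        sd, nd = ng86_path_oracle(ca, cb)
        Sd += sd
        Nd += nd
    N = 3 * n - S

    def jc(p):
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1 - 4 * p / 3)

    return S, N, Sd, Nd, jc(Sd / S if S else 0.0), jc(Nd / N if N else 0.0)


def percentile_oracle(focal: float, background: list[float]) -> float:
    """Sort-based mid-rank percentile with the resolution clamp."""
    srt = sorted(background)
    n = len(srt)
    less = sum(1 for x in srt if x < focal)
    equal = sum(1 for x in srt if x == focal)
    pct = 100.0 * (less + 0.5 * equal) / n
    lo, hi = 100.0 * 0.5 / n, 100.0 * (1 - 0.5 / n)
    return min(max(pct, lo), hi)


def mk_likelihood_oracle(tree, leaf_states: dict[str, int], P_of_edge) -> float:
    """Tree likelihood by exhaustive summation over ancestral states.

    ``P_of_edge(length)`` returns the k x k transition matrix for an edge.
    Only feasible for tiny trees; uniform root frequencies.
    """
    import numpy as np
    nodes = list(tree.postorder_node_iter())
    internal = [nd for nd in nodes if nd.child_nodes()]
    k = P_of_edge(1.0).shape[0]
    total = 0.0
    for assignment in itertools.product(range(k), repeat=len(internal)):
        state = {id(nd): s for nd, s in zip(internal, assignment)}
        for nd in nodes:
            if not nd.child_nodes():
                state[id(nd)] = leaf_states[nd.taxon.label]
        prob = 1.0 / k  # uniform root
        for nd in nodes:
            if nd.parent_node is None:
                continue
            P = P_of_edge(nd.edge.length or 0.0)
            prob_edge = P[state[id(nd.parent_node)], state[id(nd)]]
            prob *= prob_edge
        total += prob
    import math
    return math.log(total)
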