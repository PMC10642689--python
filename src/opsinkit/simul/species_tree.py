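"""Ultrametric species-tree sampling under the conditioned birth–death process.

Trees are drawn from the reconstructed birth–death process conditioned on the
number of extant species (Gernhard 2008, J Theor Biol 253:769): with speciation
rate λ, extinction rate μ < λ and r = λ − μ, the n − 1 speciation ages of an
n-tip reconstructed tree are i.i.d. with CDF

    F(t) = λ(1 − e^{−rt}) / (λ − μ e^{−rt}),        λ > μ
    F(t) = λt / (1 + λt),                            λ = μ

The tree is assembled by splitting a uniformly chosen extant lineage at each
successive speciation age, which yields the uniform (Yule-type) ranked
topology of the conditioned process. Trees are returned as rooted, binary,
ultrametric :class:`dendropy.Tree` objects with leaves ``s01 .. sNN`` and
internal nodes labelled ``n1 ..`` in preorder.
"""

from __future__ import annotations

import numpy as np
import dendropy


def speciation_time_cdf(t, birth: float, death: float):
    """CDF of a single speciation age under the conditioned process."""
    t = np.asarray(t, dtype=float)
    if birth == death:
        return birth * t / (1.0 + birth * t)
    r = birth - death
    x = np.exp(-r * t)
    return birth * (1.0 - x) / (birth - death * x)


def _sample_speciation_ages(n: int, birth: float, death: float,
                            rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    if birth == death:
        return u / (birth * (1.0 - u))
    r = birth - death
    x = birth * (1.0 - u) / (birth - u * death)
    return -np.log(x) / r


def label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign deterministic preorder labels n1, n2, ... to internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        node.label = f"n{i}"


def simulate_species_tree(n_species: int, birth: float, death: float,
                          seed: int) -> dendropy.Tree:
    """Sample an ultrametric species tree conditioned on ``n_species`` tips.

    Parameters
    ----------
    n_species : number of extant species (>= 2).
    birth, death : speciation and extinction rates; birth > 0, death >= 0,
        death <= birth (supercritical or critical process).
    seed : RNG seed; the same seed yields a bit-identical tree.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth <= 0:
        raise ValueError("birth rate must be > 0")
    if death < 0:
        raise ValueError("death rate must be >= 0")
    if death > birth:
        raise ValueError("conditioned sampler requires death <= birth")
    rng = np.random.default_rng(seed)

    ages = np.sort(_sample_speciation_ages(n_species - 1, birth, death, rng))

    # coalescent-style assembly: join two uniformly chosen lineages at each
    # successive speciation age (ascending), giving the exchangeable ranked
    # topology of the conditioned process
    width = len(str(n_species))
    active = [(f"s{i + 1:0{width}d}", 0.0) for i in range(n_species)]
    for age in ages:
        i, j = rng.choice(len(active), size=2, replace=False)
        sub_i, age_i = active[int(i)]
        sub_j, age_j = active[int(j)]
        joined = (f"({sub_i}:{age - age_i:.10f},{sub_j}:{age - age_j:.10f})", age)
        active = [lin for k, lin in enumerate(active) if k not in (int(i), int(j))]
        active.append(joined)
    newick = active[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    label_internal_nodes(tree)
    return tree


def tree_total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node.parent_node)


def node_age(node) -> float:
    """Age (time before present) of a node in an ultrametric tree."""
    d = 0.0
    n = node
    while n.child_nodes():
        n = n.child_nodes()[0]
        d += n.edge.length or 0.0
    return d
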