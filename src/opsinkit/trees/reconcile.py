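"""Gene-tree/species-tree reconciliation by LCA (lowest common ancestor) mapping.

Every gene-tree leaf maps to its species; every internal node maps to the
LCA of its children's mappings. A node is a duplication iff it maps to the
same species-tree node as at least one of its children, and the duplication
is assigned to the species-tree branch above that node (branches are named
by their child node: leaf label for terminal branches, internal label
otherwise). Losses follow the standard path-length count: an edge from gene
node u to child v contributes dist(M(u),M(v)) − 1 losses when u is a
speciation and dist(M(u),M(v)) when u is a duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class DuplicationCall:
    gene_leafset: frozenset[str]     # leaves under the duplication node
    species_branch: str              # branch above M(v), named by child node
    species_node_leafset: frozenset[str]
    child_leafsets: tuple[frozenset[str], frozenset[str]] = (frozenset(), frozenset())


@dataclass
class ReconciliationResult:
    duplications: list[DuplicationCall]
    losses: int
    mapping: dict = field(default_factory=dict)  # gene leafset -> species label

    @property
    def n_duplications(self) -> int:
        return len(self.duplications)

    @property
    def cost(self) -> int:
        return self.n_duplications + self.losses


def _check_binary(tree: dendropy.Tree, name: str) -> None:
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(f"{name} is not strictly binary (multifurcation)")


def _branch_name(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label if node.label else "+".join(sorted(
        lf.taxon.label for lf in node.leaf_iter()))


def reconcile(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
              leaf_map: dict[str, str]) -> ReconciliationResult:
    """LCA reconciliation of a rooted binary gene tree into the species tree.

    ``leaf_map`` sends each gene leaf label to a species leaf label; an
    unmapped gene leaf raises ValueError.
    """
    _check_binary(gene_tree, "gene tree")
    _check_binary(species_tree, "species tree")

    # species-tree bookkeeping: parents, depths, leaves
    depth: dict = {}
    parent: dict = {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
    species_leaf = {lf.taxon.label: lf for lf in species_tree.leaf_node_iter()}

    def lca(a, b):
        while depth[a] > depth[b]:
            a = parent[a]
        while depth[b] > depth[a]:
            b = parent[b]
        while a is not b:
            a, b = parent[a], parent[b]
        return a

    M: dict = {}
    dup: dict = {}
    duplications: list[DuplicationCall] = []
    mapping: dict = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in leaf_map or leaf_map[lab] not in species_leaf:
                raise ValueError(f"gene leaf {lab!r} has no species mapping")
            M[node] = species_leaf[leaf_map[lab]]
            dup[node] = False
        else:
            c1, c2 = node.child_nodes()
            M[node] = lca(M[c1], M[c2])
            dup[node] = M[node] is M[c1] or M[node] is M[c2]
            if dup[node]:
                leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
                sp_leafset = frozenset(
                    lf.taxon.label for lf in M[node].leaf_iter())
                kids = tuple(
                    frozenset(lf.taxon.label for lf in c.leaf_iter())
                    for c in (c1, c2))
                duplications.append(DuplicationCall(
                    leafset, _branch_name(M[node]), sp_leafset, kids))
        mapping[frozenset(lf.taxon.label for lf in node.leaf_iter())] = \
            _branch_name(M[node])

    losses = 0
    for node in gene_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            dist = depth[M[child]] - depth[M[node]]
            losses += dist if dup[node] else max(0, dist - 1)
    return ReconciliationResult(duplications, losses, mapping)


class _FastReconciler:
    """Duplication+loss cost over all rootings of an unrooted gene topology.

    Works on a plain adjacency representation so that NNI search does not
    pay dendropy's object overhead in its inner loop.
    """

    def __init__(self, species_tree: dendropy.Tree, leaf_map: dict[str, str]):
        self.sp_parent: list[int] = []
        self.sp_depth: list[int] = []
        index: dict = {}
        for node in species_tree.preorder_node_iter():
            i = len(self.sp_parent)
            index[id(node)] = i
            if node.parent_node is None:
                self.sp_parent.append(-1)
                self.sp_depth.append(0)
            else:
                p = index[id(node.parent_node)]
                self.sp_parent.append(p)
                self.sp_depth.append(self.sp_depth[p] + 1)
        self.sp_of_leaf_label = {
            lf.taxon.label: index[id(lf)]
            for lf in species_tree.leaf_node_iter()}
        self.leaf_map = leaf_map

    def species_index(self, gene_label: str) -> int:
        sp = self.leaf_map.get(gene_label)
        if sp is None or sp not in self.sp_of_leaf_label:
            raise ValueError(f"gene leaf {gene_label!r} has no species mapping")
        return self.sp_of_leaf_label[sp]

    def _lca(self, a: int, b: int) -> int:
        da, db = self.sp_depth[a], self.sp_depth[b]
        while da > db:
            a = self.sp_parent[a]
            da -= 1
        while db > da:
            b = self.sp_parent[b]
            db -= 1
        while a != b:
            a, b = self.sp_parent[a], self.sp_parent[b]
        return a

    def best_rooting(self, adj: dict, leaves: dict) -> tuple[int, tuple]:
        """(min dup+loss cost, best root edge) over all rootings.

        Uses a directed-edge DP: for each directed edge (u -> v) the LCA
        mapping and internal cost of the subtree hanging off v away from u
        is memoized, so evaluating every rooting is linear in the number of
        edges.
        """
        memo: dict = {}
        depth = self.sp_depth

        def up(u, v):
            key = (u, v)
            if key in memo:
                return memo[key]
            kids = [n for n in adj[v] if n != u]
            if not kids:
                res = (leaves[v], 0)
            else:
                ms, cost = [], 0
                for k in kids:
                    m_k, c_k = up(v, k)
                    ms.append(m_k)
                    cost += c_k
                m = ms[0]
                for x in ms[1:]:
                    m = self._lca(m, x)
                dup = any(x == m for x in ms)
                if dup:
                    cost += 1
                for x in ms:
                    d = depth[x] - depth[m]
                    cost += d if dup else max(0, d - 1)
                res = (m, cost)
            memo[key] = res
            return res

        best = None
        for a, b in _edge_list(adj):
            m1, c1 = up(a, b)
            m2, c2 = up(b, a)
            m = self._lca(m1, m2)
            cost = c1 + c2
            if m1 == m or m2 == m:
                cost += 1 + (depth[m1] - depth[m]) + (depth[m2] - depth[m])
            else:
                cost += max(0, depth[m1] - depth[m] - 1) \
                    + max(0, depth[m2] - depth[m] - 1)
            if best is None or cost < best[0]:
                best = (cost, (a, b))
        return best


def _edge_list(adj: dict) -> list[tuple]:
    seen = set()
    out = []
    for a, nbrs in adj.items():
        for b in nbrs:
            key = (a, b) if a < b else (b, a)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def _tree_to_adjacency(tree: dendropy.Tree):
    """Unrooted adjacency (ints), leaf -> species-agnostic gene labels."""
    adj: dict = {}
    labels: dict = {}
    index: dict = {}

    def nid(node):
        if id(node) not in index:
            index[id(node)] = len(index)
            adj[index[id(node)]] = set()
        return index[id(node)]

    for node in tree.preorder_node_iter():
        i = nid(node)
        if node.is_leaf():
            labels[i] = node.taxon.label
        if node.parent_node is not None:
            p = nid(node.parent_node)
            adj[p].add(i)
            adj[i].add(p)
    # suppress the rooting trifurcation artifact: nothing to do, adjacency
    # already unrooted; but remove degree-2 seed if the tree was rooted
    seed = index[id(tree.seed_node)]
    if len(adj[seed]) == 2:
        a, b = sorted(adj[seed])
        adj[a].discard(seed)
        adj[b].discard(seed)
        adj[a].add(b)
        adj[b].add(a)
        del adj[seed]
    return adj, labels


def _adjacency_to_rooted_newick(adj: dict, labels: dict, root_edge) -> str:
    u, v = root_edge

    def render(node, parent):
        kids = [n for n in adj[node] if n != parent]
        if not kids:
            return labels[node]
        return "(" + ",".join(render(k, node) for k in kids) + ")"

    return f"({render(u, v)},{render(v, u)});"


def refine_gene_tree_nni(gene_tree: dendropy.Tree,
                         species_tree: dendropy.Tree,
                         leaf_map: dict[str, str],
                         short_edge: float | None = None,
                         max_iter: int = 30
                         ) -> tuple[dendropy.Tree, ReconciliationResult]:
    """Reconciliation-guided NNI refinement of an unrooted gene tree.

    Distance-based gene trees misresolve branches carrying few
    substitutions, and a spurious resolution shows up as extra duplications
    and losses under LCA reconciliation. Starting from the input topology,
    NNI rearrangements are accepted when they strictly lower the
    duplication + loss cost of the optimally rooted reconciliation (the
    rearrangement idea of species-tree-aware gene-tree correction tools).
    Because acceptance requires a strict cost drop, well-supported
    duplication clades — whose cost cannot be reduced by any topology —
    are preserved. ``short_edge`` is accepted for API compatibility and
    ignored: gating by branch length would block exactly the rearrangements
    around old speciations that misplace recent duplicates.

    Returns the optimally rooted refined tree and its reconciliation.
    """
    if len(gene_tree.leaf_nodes()) < 3:
        t = gene_tree.clone(depth=1)
        t.is_rooted = True
        return t, reconcile(t, species_tree, leaf_map)
    eng = _FastReconciler(species_tree, leaf_map)
    adj, labels = _tree_to_adjacency(gene_tree)
    leaves = {i: eng.species_index(lab) for i, lab in labels.items()}

    best_cost, best_edge = eng.best_rooting(adj, leaves)

    def nni_pass() -> bool:
        """Steepest-descent sweep over all NNI rearrangements."""
        nonlocal best_cost, best_edge
        best_move = None
        for (u, v) in _edge_list(adj):
            if u not in adj or v not in adj:
                continue
            if len(adj[u]) < 3 or len(adj[v]) < 3:
                continue  # NNI needs an internal-internal edge
            for a in [n for n in adj[u] if n != v]:
                for c in [n for n in adj[v] if n != u]:
                    # swap subtrees a and c across edge (u, v)
                    adj[u].discard(a); adj[a].discard(u)
                    adj[v].discard(c); adj[c].discard(v)
                    adj[u].add(c); adj[c].add(u)
                    adj[v].add(a); adj[a].add(v)
                    cost, edge = eng.best_rooting(adj, leaves)
                    if cost < best_cost and (best_move is None
                                             or cost < best_move[0]):
                        best_move = (cost, edge, (u, v, a, c))
                    # revert
                    adj[u].discard(c); adj[c].discard(u)
                    adj[v].discard(a); adj[a].discard(v)
                    adj[u].add(a); adj[a].add(u)
                    adj[v].add(c); adj[c].add(v)
        if best_move is None:
            return False
        cost, edge, (u, v, a, c) = best_move
        adj[u].discard(a); adj[a].discard(u)
        adj[v].discard(c); adj[c].discard(v)
        adj[u].add(c); adj[c].add(u)
        adj[v].add(a); adj[a].add(v)
        best_cost, best_edge = cost, edge
        return True

    def subtree_sets() -> dict:
        sets: dict = {}
        for uv in _edge_list(adj):
            for (p, s0) in (uv, uv[::-1]):
                sub = {s0}
                stack = [s0]
                while stack:
                    n0 = stack.pop()
                    for nb in adj[n0]:
                        if nb != p and nb not in sub:
                            sub.add(nb)
                            stack.append(nb)
                sets[(p, s0)] = sub
        return sets

    def swap_pass() -> bool:
        """Exchange two disjoint subtrees (a2<->b1 style quartet repairs).

        Equivalent to two coordinated SPRs; rescues the misresolved
        duplication quartet ((a1,a2),(b1,b2)) -> ((a1,b1),(a2,b2)) — with
        a's and b's leaves or whole clades — which no single NNI or SPR
        can reach through strictly improving steps.
        """
        nonlocal best_cost, best_edge
        sets = subtree_sets()
        edges = sorted(sets)
        for i, (p1, s1) in enumerate(edges):
            set1 = sets[(p1, s1)]
            for (p2, s2) in edges[i + 1:]:
                set2 = sets[(p2, s2)]
                if p1 in set2 or p2 in set1 or set1 & set2:
                    continue
                if p1 == p2 or (p1, s1) == (s2, p2):
                    continue
                adj[p1].discard(s1); adj[s1].discard(p1)
                adj[p2].discard(s2); adj[s2].discard(p2)
                adj[p1].add(s2); adj[s2].add(p1)
                adj[p2].add(s1); adj[s1].add(p2)
                cost, edge = eng.best_rooting(adj, leaves)
                if cost < best_cost:
                    best_cost, best_edge = cost, edge
                    return True
                adj[p1].discard(s2); adj[s2].discard(p1)
                adj[p2].discard(s1); adj[s1].discard(p2)
                adj[p1].add(s1); adj[s1].add(p1)
                adj[p2].add(s2); adj[s2].add(p2)
        return False

    def spr_pass() -> bool:
        """Subtree prune-and-regraft; escapes NNI/leaf-swap local optima."""
        nonlocal best_cost, best_edge, adj
        if len(labels) < 4:
            return False
        for (p, s0) in [e for uv in _edge_list(adj) for e in (uv, uv[::-1])]:
            # subtree = component containing s0 after cutting edge (p, s0)
            sub = {s0}
            stack = [s0]
            while stack:
                n0 = stack.pop()
                for nb in adj[n0]:
                    if nb != p and nb not in sub:
                        sub.add(nb)
                        stack.append(nb)
            rest = set(adj) - sub
            if len(rest) < 4:      # nothing non-trivial to regraft onto
                continue
            base = {k: set(v) for k, v in adj.items() if k in rest}
            base[p].discard(s0)
            if len(base[p]) == 2:  # splice the degree-2 node
                x, y = sorted(base[p])
                base[x].discard(p); base[y].discard(p)
                base[x].add(y); base[y].add(x)
                del base[p]
                forbidden = (x, y) if x < y else (y, x)
            else:
                forbidden = None
            fresh = max(adj) + 1
            sub_adj = {k: set(v) for k, v in adj.items() if k in sub}
            sub_adj[s0].discard(p)
            for e in _edge_list(base):
                if e == forbidden:
                    continue
                x, y = e
                cand = {k: set(v) for k, v in base.items()}
                cand.update({k: set(v) for k, v in sub_adj.items()})
                cand[x].discard(y); cand[y].discard(x)
                cand[fresh] = {x, y, s0}
                cand[x].add(fresh); cand[y].add(fresh)
                cand[s0].add(fresh)
                cost, edge = eng.best_rooting(cand, leaves)
                if cost < best_cost:
                    best_cost, best_edge = cost, edge
                    adj = cand
                    return True
        return False

    for _ in range(max_iter):
        if nni_pass():
            continue
        if swap_pass():
            continue
        if spr_pass():
            continue
        break

    newick = _adjacency_to_rooted_newick(adj, labels, best_edge)
    rooted = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
    rooted.is_rooted = True
    return rooted, reconcile(rooted, species_tree, leaf_map)


def root_by_reconciliation(gene_tree: dendropy.Tree,
                           species_tree: dendropy.Tree,
                           leaf_map: dict[str, str]
                           ) -> tuple[dendropy.Tree, ReconciliationResult]:
    """Root an unrooted gene tree to minimize duplications + losses.

    Tries every branch as the root position (gene trees here are small) and
    returns the rooting of minimal reconciliation cost; ties break toward
    the first minimal edge in a deterministic preorder edge enumeration.
    """
    best = None
    edges = [e for e in gene_tree.preorder_edge_iter()
             if e.head_node.parent_node is not None]
    for k in range(len(edges)):
        t = gene_tree.clone(depth=1)
        t_edges = [e for e in t.preorder_edge_iter()
                   if e.head_node.parent_node is not None]
        edge = t_edges[k]
        half = (edge.length or 0.0) / 2.0
        t.is_rooted = True
        t.reroot_at_edge(edge, length1=half, length2=half,
                         suppress_unifurcations=True)
        if len(t.seed_node.child_nodes()) != 2:
            continue
        try:
            res = reconcile(t, species_tree, leaf_map)
        except ValueError:
            continue
        if best is None or res.cost < best[1].cost:
            best = (t, res)
    if best is None:
        raise ValueError("no valid rooting found")
    return best
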