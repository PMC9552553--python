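"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles — fresh leaf
traversals, exhaustive enumeration, closed-form summation — deliberately
avoiding the code paths under test.
"""

from __future__ import annotations

import math
import random

from phylotrg.phylo_io import GeneTree, SpeciesTree, TreeNode


def fresh_leaf_species(node: TreeNode) -> set[str]:
    """Species below a gene-tree node by a from-scratch traversal."""
    if node.is_leaf:
        return {node.species}
    out: set[str] = set()
    for child in node.children:
        out |= fresh_leaf_species(child)
    return out


def brute_force_events(tree: GeneTree) -> dict[int, str]:
    """Species-overlap calls recomputing leaf species sets at every node."""
    calls: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        dup = False
        kids = node.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                if fresh_leaf_species(kids[i]) & fresh_leaf_species(kids[j]):
                    dup = True
        calls[id(node)] = "duplication" if dup else "speciation"
    return calls


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact summation."""
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / math.comb(N, n)


def fresh_clade(node: TreeNode) -> set[str]:
    if node.is_leaf:
        return {node.label}
    out: set[str] = set()
    for child in node.children:
        out |= fresh_clade(child)
    return out


def brute_lca_duplications(tree: GeneTree, sp_tree: SpeciesTree) -> int:
    """LCA-reconciliation duplication count by smallest-covering-clade
    search at every node."""
    sp_nodes = list(sp_tree.postorder())

    def smallest_clade(species: set[str]) -> TreeNode:
        best = None
        for node in sp_nodes:
            clade = fresh_clade(node)
            if species <= clade and (best is None
                                     or len(clade) < len(fresh_clade(best))):
                best = node
        return best

    dups = 0
    for node in tree.postorder():
        if node.is_leaf:
            continue
        m = smallest_clade(fresh_leaf_species(node))
        for child in node.children:
            if smallest_clade(fresh_leaf_species(child)) is m:
                dups += 1
                break
    return dups


def enumerate_rooted_topologies(taxa):
    """All rooted binary topologies by recursive bipartition (the smallest
    taxon pinned to the left side, so each topology appears once)."""
    taxa = sorted(taxa)

    def rec(items):
        if len(items) == 1:
            yield items[0]
            return
        pivot, rest = items[0], items[1:]
        for mask in range(2 ** len(rest) - 1):
            left = [pivot] + [rest[i] for i in range(len(rest))
                              if mask >> i & 1]
            right = [rest[i] for i in range(len(rest))
                     if not mask >> i & 1]
            for lt in rec(left):
                for rt in rec(right):
                    yield (lt, rt)

    return list(rec(taxa))


def dollo_min_losses(presence: set[str], sp_tree: SpeciesTree) -> int:
    """Minimum number of loss nodes consistent with a single gain, by
    exhaustive enumeration of loss-node subsets."""
    sp_nodes = list(sp_tree.postorder())
    gain = None
    for node in sp_nodes:
        clade = fresh_clade(node)
        if presence <= clade and (gain is None
                                  or len(clade) < len(fresh_clade(gain))):
            gain = node
    below = [n for n in gain.postorder() if n is not gain]
    leaves = [n for n in gain.postorder() if n.is_leaf]

    def survives(leaf: TreeNode, losses: set[int]) -> bool:
        node = leaf
        while node is not gain:
            if id(node) in losses:
                return False
            node = node.parent
        return True

    best = None
    for mask in range(2 ** len(below)):
        losses = {id(below[i]) for i in range(len(below)) if mask >> i & 1}
        surviving = {l.label for l in leaves if survives(l, losses)}
        if surviving == presence:
            size = len(losses)
            if best is None or size < best:
                best = size
    return best


def random_gene_tree(rng: random.Random, n_leaves: int,
                     species_pool) -> GeneTree:
    """Random rooted binary gene tree with species drawn (with replacement)
    from the pool; leaf labels g<i>_<species>."""
    nodes = []
    for i in range(n_leaves):
        sp = species_pool[rng.randrange(len(species_pool))]
        nodes.append(TreeNode(label=f"g{i}_{sp}"))
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree = GeneTree(nodes[0])
    tree.explicitly_rooted = True
    return tree
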