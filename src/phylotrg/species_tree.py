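"""Duplication-minimizing species trees and supermatrix assembly.

A candidate species topology is scored by the classical gene-duplication
(LCA reconciliation) cost: each gene-tree node maps to the species-tree MRCA
of its leaf species, and a node is a duplication when it maps to the same
species-tree node as one of its children.  The score of a topology is the
sum of duplication events over a gene-tree collection, with each unrooted
gene tree rooted at the edge minimizing its own count.  The search either
enumerates all rooted binary topologies (small taxon sets) or hill-climbs
through nearest-neighbour-interchange moves.

The module also selects near-universal single-copy families and
concatenates their alignment blocks into a partitioned supermatrix for
downstream maximum-likelihood inference by external tools.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .phylo_io import GeneTree, SpeciesTree, TreeNode
from .reconciliation import canonical_newick, edge_rootings

__all__ = [
    "TopologyScore",
    "Supermatrix",
    "duplication_score",
    "lca_duplication_count",
    "search_min_dup",
    "all_rooted_topologies",
    "select_single_copy",
    "concatenate",
]

GAP = "-"


# ---------------------------------------------------------------------------
# LCA-reconciliation duplication cost
# ---------------------------------------------------------------------------

def _sp_index(sp_tree: SpeciesTree):
    cached = getattr(sp_tree, "_lca_index", None)
    if cached is not None:
        return cached
    depth: dict[int, int] = {}
    parent: dict[int, TreeNode | None] = {id(sp_tree.root): None}
    leaf_by_species: dict[str, TreeNode] = {}
    stack = [(sp_tree.root, 0)]
    while stack:
        node, d = stack.pop()
        depth[id(node)] = d
        if node.is_leaf:
            leaf_by_species[node.label] = node
        for child in node.children:
            parent[id(child)] = node
            stack.append((child, d + 1))
    sp_tree._lca_index = (depth, parent, leaf_by_species)
    return sp_tree._lca_index


def _pair_mrca(a: TreeNode, b: TreeNode, depth, parent) -> TreeNode:
    while depth[id(a)] > depth[id(b)]:
        a = parent[id(a)]
    while depth[id(b)] > depth[id(a)]:
        b = parent[id(b)]
    while a is not b:
        a = parent[id(a)]
        b = parent[id(b)]
    return a


def lca_duplication_count(tree: GeneTree, sp_tree: SpeciesTree) -> int:
    """Duplication events of one rooted gene tree under LCA reconciliation
    with ``sp_tree`` (a node is a duplication iff it maps to the same
    species-tree node as at least one of its children)."""
    depth, parent, leaf_by_species = _sp_index(sp_tree)
    missing = tree.species - sp_tree.species
    if missing:
        raise DataError(
            f"gene-tree species absent from species tree: {sorted(missing)}")
    mapping: dict[int, TreeNode] = {}
    dups = 0
    for node in tree.postorder():
        if node.is_leaf:
            mapping[id(node)] = leaf_by_species[node.species]
            continue
        m = mapping[id(node.children[0])]
        for child in node.children[1:]:
            m = _pair_mrca(m, mapping[id(child)], depth, parent)
        mapping[id(node)] = m
        if any(mapping[id(c)] is m for c in node.children):
            dups += 1
    return dups


@dataclass
class TopologyScore:
    """A species topology with its total reconciliation-duplication cost and
    the per-gene-tree breakdown (same order as the input collection)."""
    topology: SpeciesTree
    total: int
    breakdown: list[int]


def duplication_score(sp_tree: SpeciesTree, gene_trees: Iterable[GeneTree],
                      rooting: str = "fixed") -> TopologyScore:
    """Score a candidate species tree: sum over gene trees of the LCA
    duplication count.

    ``rooting="fixed"`` (default) reconciles each gene tree as given —
    phylome trees arrive rooted, and keeping their roots makes the
    species-tree root identifiable.  ``rooting="optimal"`` re-roots each
    gene tree at its count-minimizing edge per candidate topology; note the
    score then becomes invariant to where the candidate itself is rooted.
    """
    if rooting not in ("fixed", "optimal"):
        raise ConfigError(f"rooting must be 'fixed' or 'optimal', "
                          f"got {rooting!r}")
    breakdown = []
    for gt in gene_trees:
        if rooting == "optimal" and len(gt.leaves()) > 2:
            best = min(lca_duplication_count(r, sp_tree)
                       for r in edge_rootings(gt))
        else:
            best = lca_duplication_count(gt, sp_tree)
        breakdown.append(best)
    return TopologyScore(sp_tree, sum(breakdown), breakdown)


# ---------------------------------------------------------------------------
# Topology enumeration and NNI search
# ---------------------------------------------------------------------------

Topo = object  # nested 2-tuples of species labels


def _insertions(top, leaf):
    yield (top, leaf)
    if isinstance(top, tuple):
        left, right = top
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def all_rooted_topologies(taxa: Iterable[str]):
    """Every rooted binary topology over ``taxa`` as nested 2-tuples
    ((2n-3)!! of them: 3 taxa → 3, 4 → 15, 5 → 105)."""
    taxa = sorted(set(taxa))
    if len(taxa) < 2:
        raise ConfigError("need at least 2 taxa")
    tops = [taxa[0]]
    for leaf in taxa[1:]:
        tops = [t for base in tops for t in _insertions(base, leaf)]
    return tops


def _topo_to_tree(top) -> SpeciesTree:
    def build(t) -> TreeNode:
        if isinstance(t, tuple):
            node = TreeNode()
            node.add_child(build(t[0]))
            node.add_child(build(t[1]))
            return node
        return TreeNode(label=t)
    return SpeciesTree(build(top))


def _canon(top):
    if isinstance(top, tuple):
        a, b = _canon(top[0]), _canon(top[1])
        return (a, b) if str(a) <= str(b) else (b, a)
    return top


def _nni_neighbors(top):
    """Rooted NNI neighbourhood: at every internal edge swap one grandchild
    with the sibling subtree."""
    out = []
    if not isinstance(top, tuple):
        return out
    left, right = top
    if isinstance(left, tuple):
        a, b = left
        out += [((a, right), b), ((b, right), a)]
    if isinstance(right, tuple):
        a, b = right
        out += [(a, (b, left)), (b, (a, left))]
    for t in _nni_neighbors(left):
        out.append((t, right))
    for t in _nni_neighbors(right):
        out.append((left, t))
    return out


def _caterpillar(taxa: Sequence[str]):
    top = taxa[0]
    for leaf in taxa[1:]:
        top = (top, leaf)
    return top


def _random_topology(taxa: Sequence[str], rng: random.Random):
    top = taxa[0]
    for leaf in taxa[1:]:
        options = list(_insertions(top, leaf))
        top = options[rng.randrange(len(options))]
    return top


def search_min_dup(gene_trees: Iterable[GeneTree],
                   taxa: Iterable[str] | None = None,
                   mode: str = "exhaustive", rooting: str = "fixed",
                   n_starts: int = 5, seed: int = 0,
                   max_exhaustive_taxa: int = 7) -> TopologyScore:
    """Search for the species topology minimizing total reconciliation
    duplications (the DupTree criterion).

    ``exhaustive`` enumerates every rooted binary topology (refused above
    ``max_exhaustive_taxa`` taxa — switch to ``nni``); ``nni`` hill-climbs
    from a deterministic caterpillar start plus ``n_starts`` seeded random
    restarts, with lexicographic-newick tie-breaking, and always returns a
    topology scoring no worse than its start.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise DataError("search_min_dup needs at least one gene tree")
    if taxa is None:
        taxa = set().union(*(gt.species for gt in gene_trees))
    taxa = sorted(set(taxa))

    def score_topo(top) -> TopologyScore:
        return duplication_score(_topo_to_tree(top), gene_trees, rooting)

    if mode == "exhaustive":
        if len(taxa) > max_exhaustive_taxa:
            raise ConfigError(
                f"exhaustive enumeration over {len(taxa)} taxa is "
                f"intractable (> {max_exhaustive_taxa}); use mode='nni'")
        best = None
        for top in all_rooted_topologies(taxa):
            sc = score_topo(top)
            key = (sc.total, canonical_newick(sc.topology.root))
            if best is None or key < best[0]:
                best = (key, sc)
        return best[1]

    if mode == "nni":
        rng = random.Random(seed)
        starts = [_caterpillar(taxa)]
        starts += [_random_topology(taxa, rng) for _ in range(n_starts)]
        overall = None
        for start in starts:
            current = _canon(start)
            current_sc = score_topo(current)
            while True:
                best_nb = None
                for nb in {_canon(t) for t in _nni_neighbors(current)}:
                    sc = score_topo(nb)
                    key = (sc.total, canonical_newick(sc.topology.root))
                    if best_nb is None or key < best_nb[0]:
                        best_nb = (key, nb, sc)
                if best_nb is None or best_nb[2].total >= current_sc.total:
                    break
                current, current_sc = best_nb[1], best_nb[2]
            key = (current_sc.total, canonical_newick(current_sc.topology.root))
            if overall is None or key < overall[0]:
                overall = (key, current_sc)
        return overall[1]

    raise ConfigError(f"unknown search mode {mode!r}")


# ---------------------------------------------------------------------------
# Single-copy family selection
# ---------------------------------------------------------------------------

def select_single_copy(families: Mapping[str, Mapping[str, int]] | pd.DataFrame,
                       min_species: int, total_species: int) -> list[str]:
    """Families that are strictly single copy (≤1 member per species) and
    present in at least ``min_species`` of the ``total_species`` species.

    ``families`` maps family → {species: copy count}, or is a family ×
    species count DataFrame.
    """
    if min_species > total_species:
        raise ConfigError("min_species cannot exceed total_species")
    if isinstance(families, pd.DataFrame):
        families = {fam: {sp: int(c) for sp, c in row.items() if c > 0}
                    for fam, row in families.iterrows()}
    selected = []
    for fam, counts in families.items():
        if any(c > 1 for c in counts.values()):
            continue
        n_single = sum(1 for c in counts.values() if c == 1)
        if n_single >= min_species:
            selected.append(fam)
    return selected


# ---------------------------------------------------------------------------
# Supermatrix concatenation
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Concatenated residue matrix with partition bookkeeping.

    ``partitions`` maps family → [start, end) in 0-based half-open
    coordinates; taxa missing from a family are fully gap-padded there and
    recorded in ``missing``.
    """
    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]
    missing: dict[str, set[str]]  # taxon -> families absent for it

    @property
    def width(self) -> int:
        return max((end for _, end in self.partitions.values()), default=0)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{self.rows[taxon]}\n")

    def write_partitions(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tstart\tend\n")
            for fam, (start, end) in self.partitions.items():
                fh.write(f"{fam}\t{start}\t{end}\n")


def concatenate(alignments: Mapping[str, Mapping[str, str]],
                taxa_order: Sequence[str] | None = None) -> Supermatrix:
    """Concatenate per-family trimmed alignment blocks into a supermatrix.

    ``alignments`` maps family → {taxon: aligned sequence}; within a family
    all sequences must share one length (mismatch raises, naming the
    family).  Total width is the sum of family widths.
    """
    if taxa_order is None:
        taxa_order = sorted({t for block in alignments.values()
                             for t in block})
    taxa_order = list(taxa_order)
    partitions: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa_order}
    missing: dict[str, set[str]] = {t: set() for t in taxa_order}
    cursor = 0
    for fam, block in alignments.items():
        widths = {len(seq) for seq in block.values()}
        if len(widths) > 1:
            raise DataError(
                f"family {fam!r} has unequal sequence lengths: "
                f"{sorted(widths)}")
        width = widths.pop() if widths else 0
        for taxon in taxa_order:
            if taxon in block:
                chunks[taxon].append(block[taxon])
            else:
                chunks[taxon].append(GAP * width)
                missing[taxon].add(fam)
        partitions[fam] = (cursor, cursor + width)
        cursor += width
    rows = {t: "".join(parts) for t, parts in chunks.items()}
    return Supermatrix(taxa_order, rows, partitions, missing)
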