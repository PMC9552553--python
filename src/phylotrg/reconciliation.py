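"""Gene-tree/species-tree reconciliation by species overlap.

The species-overlap rule labels an internal gene-tree node a *duplication*
when its daughter partitions share at least one species, and a *speciation*
otherwise.  The overlap score of a node is ``|intersection| / |union|`` of
the daughter species sets, so the default cutoff of 0.0 reproduces the plain
"any shared species" rule while higher cutoffs allow sensitivity analyses.

On top of event calling this module maps duplications onto species-tree
nodes (the MRCA of the union of the daughter species sets), aggregates
per-node duplication ratios across a collection of gene trees, extracts
ortholog/paralog relations, and places gene gains and losses on the species
tree under single-gain (Dollo) parsimony.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError, TreeStateError
from .phylo_io import GeneTree, SpeciesTree, TreeNode

__all__ = [
    "NodeEvent",
    "EventTable",
    "DuplicationProfile",
    "GainLossMap",
    "HomologyRelations",
    "annotate_events",
    "root_gene_tree",
    "edge_rootings",
    "map_duplications",
    "duplication_ratios",
    "extract_relations",
    "infer_gain_loss",
    "clade_name",
    "canonical_newick",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


def clade_name(tree: SpeciesTree, node: TreeNode) -> str:
    """Stable printable name for a species-tree node: its label if present,
    otherwise the sorted species of its clade joined by '|'."""
    if node.label:
        return node.label
    return "|".join(sorted(tree.leafset(node)))


def canonical_newick(node: TreeNode) -> str:
    """Topology-only newick with children sorted recursively; used for
    deterministic tie-breaking among equal-score trees."""
    if node.is_leaf:
        return node.label or ""
    parts = sorted(canonical_newick(c) for c in node.children)
    return "(" + ",".join(parts) + ")"


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeEvent:
    """Speciation/duplication call at one internal gene-tree node."""
    node: TreeNode
    event: str
    child_species: tuple[frozenset[str], ...]
    overlap: frozenset[str]
    score: float

    @property
    def species(self) -> frozenset[str]:
        return frozenset().union(*self.child_species)


class EventTable:
    """One :class:`NodeEvent` per internal node of an annotated gene tree."""

    def __init__(self, tree: GeneTree, events: Sequence[NodeEvent],
                 overlap_cutoff: float):
        self.tree = tree
        self.events = list(events)
        self.overlap_cutoff = overlap_cutoff
        self._by_node = {id(e.node): e for e in self.events}

    def event_at(self, node: TreeNode) -> NodeEvent:
        return self._by_node[id(node)]

    def duplications(self) -> list[NodeEvent]:
        return [e for e in self.events if e.event == DUPLICATION]

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.event == DUPLICATION)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.events):
            rows.append({
                "node": i,
                "event": e.event,
                "overlap_score": e.score,
                "overlap": "|".join(sorted(e.overlap)),
                "species": "|".join(sorted(e.species)),
            })
        return pd.DataFrame(rows,
                            columns=["node", "event", "overlap_score",
                                     "overlap", "species"])


def annotate_events(tree: GeneTree, overlap_cutoff: float = 0.0) -> EventTable:
    """Call speciation/duplication at every internal node by species overlap.

    A node is a duplication iff its overlap score exceeds ``overlap_cutoff``;
    with the default cutoff 0.0 any species shared between daughter
    partitions triggers a duplication call.  Multifurcating nodes are scored
    over all pairs of child partitions (the maximum pairwise score decides).

    Raises :class:`~phylotrg.errors.TreeStateError` when the tree is not
    rooted (a root with more than two children that was not produced by an
    explicit rooting step).
    """
    if not 0.0 <= overlap_cutoff < 1.0:
        raise ConfigError("overlap_cutoff must be in [0, 1)")
    n_leaves = sum(1 for _ in tree.leaves())
    if (len(tree.root.children) > 2 and n_leaves > 2
            and not getattr(tree, "explicitly_rooted", False)):
        raise TreeStateError(
            "gene tree appears unrooted (root with >2 children); apply "
            "root_gene_tree first or mark it explicitly_rooted")
    species_of: dict[int, frozenset[str]] = {}
    events: list[NodeEvent] = []
    for node in tree.postorder():
        if node.is_leaf:
            species_of[id(node)] = frozenset([node.species])
            continue
        child_sets = tuple(species_of[id(c)] for c in node.children)
        species_of[id(node)] = frozenset().union(*child_sets)
        best_score = 0.0
        overlap: frozenset[str] = frozenset()
        for a, b in itertools.combinations(child_sets, 2):
            inter = a & b
            if inter:
                score = len(inter) / len(a | b)
                if score > best_score:
                    best_score = score
                overlap = overlap | inter
        event = DUPLICATION if best_score > overlap_cutoff and overlap else SPECIATION
        events.append(NodeEvent(node, event, child_sets, overlap, best_score))
    return EventTable(tree, events, overlap_cutoff)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _unrooted_graph(root: TreeNode):
    """Undirected adjacency of the tree, suppressing a degree-2 root."""
    adj: dict[int, list[TreeNode]] = {}
    lengths: dict[frozenset[int], float | None] = {}
    nodes: dict[int, TreeNode] = {}

    def connect(u: TreeNode, v: TreeNode, length):
        adj.setdefault(id(u), []).append(v)
        adj.setdefault(id(v), []).append(u)
        lengths[frozenset((id(u), id(v)))] = length
        nodes[id(u)] = u
        nodes[id(v)] = v

    for node in root.postorder():
        for child in node.children:
            connect(node, child, child.length)
    if len(root.children) == 2:
        a, b = root.children
        la = lengths.pop(frozenset((id(root), id(a))))
        lb = lengths.pop(frozenset((id(root), id(b))))
        adj[id(a)] = [n for n in adj[id(a)] if id(n) != id(root)]
        adj[id(b)] = [n for n in adj[id(b)] if id(n) != id(root)]
        del adj[id(root)]
        nodes.pop(id(root), None)
        total = None
        if la is not None or lb is not None:
            total = (la or 0.0) + (lb or 0.0)
        connect(a, b, total)
    return adj, lengths, nodes


def _grow(node: TreeNode, come_from: TreeNode | None,
          adj, lengths) -> TreeNode:
    out = TreeNode(node.label if node.is_leaf else None)
    out.species = node.species
    out.support = node.support
    for nb in adj[id(node)]:
        if come_from is not None and id(nb) == id(come_from):
            continue
        child = _grow(nb, node, adj, lengths)
        child.length = lengths.get(frozenset((id(node), id(nb))))
        out.add_child(child)
    return out


def edge_rootings(tree: GeneTree) -> list[GeneTree]:
    """All rooted trees obtained by placing the root on each edge of the
    unrooted version of ``tree`` (degree-2 root suppressed)."""
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise DataError("cannot root a tree with fewer than 2 leaves")
    if len(leaves) == 2:
        out = tree.copy()
        out.explicitly_rooted = True
        return [out]
    adj, lengths, nodes = _unrooted_graph(tree.root)
    seen = set()
    rootings = []
    for uid in list(adj):
        for v in adj[uid]:
            key = frozenset((uid, id(v)))
            if key in seen:
                continue
            seen.add(key)
            rootings.append(_root_on_edge(tree, nodes[uid], v, adj, lengths))
    return rootings


def _root_on_edge(tree: GeneTree, u: TreeNode, v: TreeNode, adj, lengths,
                  dist_u: float | None = None, dist_v: float | None = None
                  ) -> GeneTree:
    """Build the rooted gene tree with the root placed on edge (u, v)."""
    root = TreeNode()
    edge = lengths.get(frozenset((id(u), id(v))))
    if dist_u is None or dist_v is None:
        dist_u = dist_v = edge / 2 if edge is not None else None
    left = _grow(u, v, adj, lengths)
    right = _grow(v, u, adj, lengths)
    left.length, right.length = dist_u, dist_v
    root.add_child(left)
    root.add_child(right)
    gt = GeneTree(root, tree.species_map, tree.seed_sequence_id)
    gt.explicitly_rooted = True
    return gt


def _path_lengths_from(start: TreeNode, adj, lengths, topological: bool
                       ) -> tuple[dict[int, float], dict[int, TreeNode]]:
    dist = {id(start): 0.0}
    pred: dict[int, TreeNode] = {}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[id(node)]:
            if id(nb) in dist:
                continue
            edge = lengths.get(frozenset((id(node), id(nb))))
            step = 1.0 if topological or edge is None else edge
            dist[id(nb)] = dist[id(node)] + step
            pred[id(nb)] = node
            stack.append(nb)
    return dist, pred


def root_gene_tree(tree: GeneTree, strategy: str = "min-duplications",
                   overlap_cutoff: float = 0.0) -> GeneTree:
    """Root (or re-root) a gene tree.

    Strategies: ``none`` (keep as-is), ``seed-farthest`` (root on the edge
    to the leaf farthest from the phylome seed sequence), ``midpoint``
    (longest-path midpoint), ``min-duplications`` (the edge rooting with the
    fewest species-overlap duplication events; verified against exhaustive
    edge enumeration).  Ties are broken by the lexicographically smallest
    canonical newick, so the result is deterministic.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise DataError("cannot root a tree with fewer than 2 leaves")
    if strategy == "none":
        out = tree.copy()
        out.explicitly_rooted = True
        return out
    if len(leaves) == 2:
        out = tree.copy()
        out.explicitly_rooted = True
        return out

    if strategy == "min-duplications":
        best = None
        for cand in edge_rootings(tree):
            ndup = annotate_events(cand, overlap_cutoff).n_duplications
            key = (ndup, canonical_newick(cand.root))
            if best is None or key < best[0]:
                best = (key, cand)
        return best[1]

    adj, lengths, _nodes = _unrooted_graph(tree.root)
    topo = not all(v is not None for v in lengths.values())

    if strategy == "seed-farthest":
        if tree.seed_sequence_id is None:
            raise ConfigError("seed-farthest rooting requires a "
                              "seed_sequence_id on the gene tree")
        seed = next((l for l in tree.leaves()
                     if l.label == tree.seed_sequence_id), None)
        if seed is None:
            raise ConfigError(
                f"seed sequence {tree.seed_sequence_id!r} is not a leaf")
        dist, _ = _path_lengths_from(seed, adj, lengths, topological=topo)
        # farthest leaf from the seed, ties broken by label
        target = max((l for l in tree.leaves() if l is not seed),
                     key=lambda l: (dist[id(l)], l.label))
        nb = adj[id(target)][0]
        return _root_on_edge(tree, target, nb, adj, lengths)

    if strategy == "midpoint":
        # double sweep: the longest leaf-to-leaf path, then its midpoint
        leaves = tree.leaves()
        d0, _ = _path_lengths_from(leaves[0], adj, lengths, topological=topo)
        a = max(leaves, key=lambda l: (d0[id(l)], l.label))
        da, pred = _path_lengths_from(a, adj, lengths, topological=topo)
        b = max(leaves, key=lambda l: (da[id(l)], l.label))
        half = da[id(b)] / 2
        # walk the a..b path (from b back via predecessors) and find the
        # edge straddling the midpoint
        path = [b]
        while path[-1] is not a:
            path.append(pred[id(path[-1])])
        path.reverse()  # a ... b
        for u, v in zip(path, path[1:]):
            if da[id(u)] <= half <= da[id(v)]:
                return _root_on_edge(tree, u, v, adj, lengths,
                                     dist_u=None if topo else half - da[id(u)],
                                     dist_v=None if topo else da[id(v)] - half)
        raise AssertionError("unreachable: midpoint edge not found")

    raise ConfigError(f"unknown rooting strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Mapping duplications to the species tree
# ---------------------------------------------------------------------------

def map_duplications(events: EventTable, sp_tree: SpeciesTree
                     ) -> dict[int, int]:
    """Assign each duplication event to the species-tree MRCA of the union
    of its daughter species sets; returns ``{id(species_node): count}``.

    Raises :class:`~phylotrg.errors.DataError` naming any gene-tree species
    missing from the species tree.
    """
    missing = events.tree.species - sp_tree.species
    if missing:
        raise DataError(
            f"gene-tree species absent from species tree: {sorted(missing)}")
    counts: Counter[int] = Counter()
    for ev in events.duplications():
        node = sp_tree.mrca(ev.species)
        counts[id(node)] += 1
    return dict(counts)


@dataclass
class DuplicationProfile:
    """Per-species-tree-node duplication counts, containing-tree counts and
    ratios (count / containing trees; undefined when no tree contains the
    node)."""
    sp_tree: SpeciesTree
    counts: dict[int, int]
    containing: dict[int, int]

    def ratio(self, node: TreeNode) -> float | None:
        trees = self.containing.get(id(node), 0)
        if trees == 0:
            return None
        return self.counts.get(id(node), 0) / trees

    @property
    def total_duplications(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.sp_tree.postorder():
            trees = self.containing.get(id(node), 0)
            rows.append({
                "node": clade_name(self.sp_tree, node),
                "duplications": self.counts.get(id(node), 0),
                "containing_trees": trees,
                "ratio": self.ratio(node),
            })
        return pd.DataFrame(rows, columns=["node", "duplications",
                                           "containing_trees", "ratio"])


def _contains_node(tree_species: frozenset[str], sp_tree: SpeciesTree,
                   node: TreeNode, rule: str) -> bool:
    if node.is_leaf:
        return node.label in tree_species
    if rule == "both-daughters":
        return all(tree_species & sp_tree.leafset(c) for c in node.children)
    if rule == "clade":
        return bool(tree_species & sp_tree.leafset(node))
    raise ConfigError(f"unknown containment rule {rule!r}")


def duplication_ratios(gene_trees: Iterable[GeneTree], sp_tree: SpeciesTree,
                       overlap_cutoff: float = 0.0,
                       expansion_cap: int | None = None,
                       containment: str = "both-daughters",
                       ) -> DuplicationProfile:
    """Duplication ratio per species-tree node over a gene-tree collection.

    The ratio divides the duplications mapped to a node by the number of
    gene trees *containing* that node.  Containment (the denominator) is a
    modelling choice: under the default ``both-daughters`` rule a tree
    contains an internal node when its species intersect both daughter
    clades — exactly the trees in which a duplication could map there; the
    looser ``clade`` rule only requires intersection with the node's clade.

    ``expansion_cap`` bounds the duplications any single gene tree can
    contribute to one node, damping large family expansions; ``None``
    disables the cap.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise DataError("duplication_ratios needs a non-empty gene-tree "
                        "collection")
    if expansion_cap is not None and expansion_cap < 0:
        raise ConfigError("expansion_cap must be non-negative or None")
    counts: Counter[int] = Counter()
    containing: Counter[int] = Counter()
    nodes = list(sp_tree.postorder())
    for gt in gene_trees:
        events = annotate_events(gt, overlap_cutoff)
        per_tree = map_duplications(events, sp_tree)
        for nid, c in per_tree.items():
            if expansion_cap is not None:
                c = min(c, expansion_cap)
            counts[nid] += c
        sp = gt.species
        for node in nodes:
            if _contains_node(sp, sp_tree, node, containment):
                containing[id(node)] += 1
    return DuplicationProfile(sp_tree, dict(counts), dict(containing))


# ---------------------------------------------------------------------------
# Ortholog / paralog relations
# ---------------------------------------------------------------------------

@dataclass
class HomologyRelations:
    """Ortholog and paralog pairs extracted from an annotated gene tree.

    ``orthologs`` rows: (gene_a, gene_b, kind) with kind in one-to-one /
    one-to-many / many-to-one / many-to-many; ``paralogs`` rows:
    (gene_a, gene_b).  Pairs are stored with gene_a < gene_b except that
    ortholog kinds keep the (a side, b side) orientation of the sorted pair.
    """
    orthologs: pd.DataFrame
    paralogs: pd.DataFrame

    def ortholog_pairs(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.orthologs[["gene_a", "gene_b"]].values))

    def one_to_one_pairs(self) -> set[tuple[str, str]]:
        sub = self.orthologs[self.orthologs["kind"] == "one-to-one"]
        return set(map(tuple, sub[["gene_a", "gene_b"]].values))

    def paralog_pairs(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.paralogs[["gene_a", "gene_b"]].values))


def extract_relations(events: EventTable) -> HomologyRelations:
    """Walk the event table: a leaf pair is orthologous iff its gene-tree
    MRCA is a speciation event, paralogous iff a duplication.

    The one-to-one flag requires each side of the pair to be the only
    sequence of its species within its daughter subtree of the MRCA.
    """
    tree = events.tree
    leaves_below: dict[int, list[TreeNode]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leaves_below[id(node)] = [node]
        else:
            leaves_below[id(node)] = [l for c in node.children
                                      for l in leaves_below[id(c)]]
    orth_rows, para_rows = [], []
    for ev in events.events:
        node = ev.node
        children = node.children
        for ca, cb in itertools.combinations(children, 2):
            la, lb = leaves_below[id(ca)], leaves_below[id(cb)]
            count_a = Counter(l.species for l in la)
            count_b = Counter(l.species for l in lb)
            for x in la:
                for y in lb:
                    a, b = sorted((x, y), key=lambda l: l.label)
                    if ev.event == DUPLICATION:
                        para_rows.append({"gene_a": a.label,
                                          "gene_b": b.label})
                        continue
                    if x.species == y.species:
                        continue  # same-species pair under speciation node
                    single_x = count_a[x.species] == 1
                    single_y = count_b[y.species] == 1
                    # orient kind on the sorted (a, b) pair
                    single_a, single_b = ((single_x, single_y)
                                          if a is x else (single_y, single_x))
                    if single_a and single_b:
                        kind = "one-to-one"
                    elif single_a:
                        kind = "one-to-many"
                    elif single_b:
                        kind = "many-to-one"
                    else:
                        kind = "many-to-many"
                    orth_rows.append({"gene_a": a.label, "gene_b": b.label,
                                      "kind": kind})
    orthologs = pd.DataFrame(orth_rows, columns=["gene_a", "gene_b", "kind"])
    paralogs = pd.DataFrame(para_rows, columns=["gene_a", "gene_b"])
    return HomologyRelations(orthologs, paralogs)


# ---------------------------------------------------------------------------
# Gains and losses (Dollo)
# ---------------------------------------------------------------------------

@dataclass
class GainLossMap:
    """Single-gain Dollo placement of each orthogroup on the species tree.

    The gain sits at the MRCA of the orthogroup's species; losses are the
    highest (closest-to-root) nodes below the gain whose entire clade lacks
    the family, so no loss is double-counted.
    """
    sp_tree: SpeciesTree
    gains: dict[str, TreeNode]
    losses: dict[str, list[TreeNode]]

    def gain_counts(self) -> Counter:
        return Counter(id(n) for n in self.gains.values())

    def loss_counts(self) -> Counter:
        return Counter(id(n) for ns in self.losses.values() for n in ns)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        gain_c = self.gain_counts()
        loss_c = self.loss_counts()
        for node in self.sp_tree.postorder():
            rows.append({
                "node": clade_name(self.sp_tree, node),
                "gains": gain_c.get(id(node), 0),
                "losses": loss_c.get(id(node), 0),
            })
        return pd.DataFrame(rows, columns=["node", "gains", "losses"])


def infer_gain_loss(presence: Mapping[str, Iterable[str]] | pd.DataFrame,
                    sp_tree: SpeciesTree) -> GainLossMap:
    """Place one gain (at the MRCA of the present species) and the minimal
    set of losses for every orthogroup.

    ``presence`` maps orthogroup → present species, or is a boolean
    orthogroup × species DataFrame.  An orthogroup with no present species
    is an error naming the group.
    """
    if isinstance(presence, pd.DataFrame):
        presence = {og: set(presence.columns[presence.loc[og].astype(bool)])
                    for og in presence.index}
    gains: dict[str, TreeNode] = {}
    losses: dict[str, list[TreeNode]] = {}
    for group, species in presence.items():
        species = frozenset(species)
        if not species:
            raise DataError(f"orthogroup {group!r} has an empty presence row")
        missing = species - sp_tree.species
        if missing:
            raise DataError(f"orthogroup {group!r} names species absent from "
                            f"the species tree: {sorted(missing)}")
        gain = sp_tree.mrca(species)
        gains[group] = gain
        group_losses: list[TreeNode] = []

        def descend(node: TreeNode) -> None:
            for child in node.children:
                if sp_tree.leafset(child) & species:
                    descend(child)
                else:
                    group_losses.append(child)

        descend(gain)
        losses[group] = group_losses
    return GainLossMap(sp_tree, gains, losses)
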