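import random

import pytest

from conftest import gene
from oracles import (
    brute_force_events,
    dollo_min_losses,
    random_gene_tree,
)
from phylotrg.errors import ConfigError, DataError, TreeStateError
from phylotrg.phylo_io import read_newick
from phylotrg.reconciliation import (
    annotate_events,
    clade_name,
    duplication_ratios,
    edge_rootings,
    extract_relations,
    infer_gain_loss,
    map_duplications,
    root_gene_tree,
)
from phylotrg.synthetic_data import simulate_family, simulate_species_tree


# ---------------------------------------------------------------------------
# event calling
# ---------------------------------------------------------------------------

def test_single_copy_tree_is_all_speciations():
    events = annotate_events(gene("((g1_A,g1_B),g1_C);"))
    assert events.n_duplications == 0
    assert all(e.event == "speciation" for e in events.events)


def test_within_species_duplication_called():
    events = annotate_events(gene("((g1_A,g2_A),g1_B);"))
    dups = events.duplications()
    assert len(dups) == 1
    assert dups[0].overlap == {"A"}
    # the duplication is the (g1_A, g2_A) cherry, not the root
    assert sorted(dups[0].node.leaf_labels()) == ["g1_A", "g2_A"]


def test_root_duplication_with_full_overlap():
    events = annotate_events(gene("((g1_A,g1_B),(g2_A,g2_B));"))
    dups = events.duplications()
    assert len(dups) == 1
    assert dups[0].node is events.tree.root
    assert dups[0].score == 1.0  # overlap {A,B} over union {A,B}
    others = [e for e in events.events if e.event == "speciation"]
    assert len(others) == 2


def test_unrooted_tree_rejected():
    tree = read_newick("(g1_A,g2_A,g1_B);", kind="gene")
    with pytest.raises(TreeStateError):
        annotate_events(tree)


def test_overlap_cutoff_monotonicity(rng):
    """Raising the overlap cutoff never increases duplication calls."""
    for _ in range(50):
        tree = random_gene_tree(rng, rng.randint(3, 15),
                                ["A", "B", "C", "D", "E"])
        counts = [annotate_events(tree, c).n_duplications
                  for c in (0.0, 0.2, 0.5, 0.8)]
        assert counts == sorted(counts, reverse=True)


def test_events_match_brute_force_oracle(rng):
    """Species-overlap calls equal an independent implementation that
    recomputes leaf species sets from scratch at every node."""
    for _ in range(150):
        tree = random_gene_tree(rng, rng.randint(3, 12),
                                ["A", "B", "C", "D", "E", "F"])
        events = annotate_events(tree)
        oracle = brute_force_events(tree)
        for ev in events.events:
            assert ev.event == oracle[id(ev.node)]


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def test_edge_rooting_enumeration_count():
    # 4-leaf unrooted tree has 5 edges, hence 5 rootings
    tree = read_newick("((g1_A,g1_B),(g2_A,g1_C));", kind="gene")
    assert len(edge_rootings(tree)) == 5


def test_min_duplication_rooting_attains_enumerated_minimum():
    tree = read_newick("((g1_A,g1_B),(g2_A,g1_C));", kind="gene")
    rooted = root_gene_tree(tree, "min-duplications")
    best = annotate_events(rooted).n_duplications
    enumerated = [annotate_events(r).n_duplications
                  for r in edge_rootings(tree)]
    assert best == min(enumerated) == 1


def test_congruent_tree_roots_to_zero_duplications(rng):
    """A single-copy gene tree congruent with the species tree has a
    zero-duplication rooting, and min-duplications finds it."""
    for seed in range(10):
        sp = simulate_species_tree(6, seed=seed)
        fam = simulate_family(sp, 0.0, 0.0, seed=seed)
        rooted = root_gene_tree(fam.tree, "min-duplications")
        assert annotate_events(rooted).n_duplications == 0


def test_rooting_trivial_cases():
    two = gene("(g1_A,g1_B);")
    for strategy in ("none", "midpoint", "min-duplications"):
        out = root_gene_tree(two, strategy)
        assert sorted(out.root.leaf_labels()) == ["g1_A", "g1_B"]
    rooted = gene("((g1_A,g1_B),g1_C);")
    assert root_gene_tree(rooted, "none").newick() == rooted.newick()


def test_seed_farthest_requires_seed():
    tree = gene("((g1_A,g1_B),g1_C);")
    with pytest.raises(ConfigError):
        root_gene_tree(tree, "seed-farthest")
    tree.seed_sequence_id = "g1_A"
    out = root_gene_tree(tree, "seed-farthest")
    # one side of the root is the leaf farthest from the seed
    sides = [set(c.leaf_labels()) for c in out.root.children]
    assert any(len(s) == 1 and s != {"g1_A"} for s in sides)


def test_midpoint_rooting_uses_branch_lengths():
    tree = read_newick("((g1_A:1,g1_B:1):1,(g1_C:1,g1_D:10):1);",
                       kind="gene")
    out = root_gene_tree(tree, "midpoint")
    # the long branch to g1_D must be split by the root
    sides = [set(c.leaf_labels()) for c in out.root.children]
    assert {"g1_D"} in sides


# ---------------------------------------------------------------------------
# mapping duplications
# ---------------------------------------------------------------------------

def test_within_species_duplication_maps_to_leaf(abc_species_tree):
    events = annotate_events(gene("((g1_A,g2_A),g1_B);"))
    counts = map_duplications(events, abc_species_tree)
    (nid, n), = counts.items()
    node = next(x for x in abc_species_tree.postorder() if id(x) == nid)
    assert node.label == "A" and n == 1


def test_cross_species_duplication_maps_to_mrca(abc_species_tree):
    events = annotate_events(gene("((g1_A,g1_B),(g2_A,g2_B));"))
    counts = map_duplications(events, abc_species_tree)
    (nid, n), = counts.items()
    node = next(x for x in abc_species_tree.postorder() if id(x) == nid)
    assert clade_name(abc_species_tree, node) == "A|B" and n == 1


def test_zero_duplication_tree_maps_nothing(abc_species_tree):
    events = annotate_events(gene("((g1_A,g1_B),g1_C);"))
    assert map_duplications(events, abc_species_tree) == {}


def test_unknown_species_is_an_error(abc_species_tree):
    events = annotate_events(gene("((g1_A,g1_Z),g1_C);"))
    with pytest.raises(DataError, match="Z"):
        map_duplications(events, abc_species_tree)


def test_duplication_count_conservation(rng):
    """Across a simulated collection, per-node mapped counts sum to the
    total number of duplication events called over all gene trees."""
    sp = simulate_species_tree(8, seed=11)
    fams = [simulate_family(sp, 0.25, 0.1, seed=i) for i in range(500)]
    trees = [f.tree for f in fams]
    total_called = sum(annotate_events(t).n_duplications for t in trees)
    profile = duplication_ratios(trees, sp)
    assert profile.total_duplications == total_called


# ---------------------------------------------------------------------------
# duplication ratios
# ---------------------------------------------------------------------------

def test_congruent_single_copy_collection_has_zero_ratios():
    sp = simulate_species_tree(6, seed=3)
    trees = [simulate_family(sp, 0.0, 0.0, seed=i).tree for i in range(10)]
    profile = duplication_ratios(trees, sp)
    for node in sp.postorder():
        ratio = profile.ratio(node)
        assert ratio is None or ratio == 0.0


def test_ratio_is_duplications_over_containing_trees(abc_species_tree):
    with_dup = gene("((g1_A,g1_B),(g2_A,g2_B));")  # 1 dup at (A,B)
    without = gene("(g1_A,g1_B);")
    profile = duplication_ratios([with_dup, without], abc_species_tree)
    ab = next(n for n in abc_species_tree.postorder()
              if clade_name(abc_species_tree, n) == "A|B")
    assert profile.ratio(ab) == 0.5


def test_ratio_one_means_one_duplication_per_gene(abc_species_tree):
    trees = [gene(f"((g{2 * i}_A,g{2 * i}_B),(g{2 * i + 1}_A,"
                  f"g{2 * i + 1}_B));") for i in range(3)]
    profile = duplication_ratios(trees, abc_species_tree)
    ab = next(n for n in abc_species_tree.postorder()
              if clade_name(abc_species_tree, n) == "A|B")
    assert profile.ratio(ab) == 1.0


def test_uncontained_node_ratio_is_undefined(abc_species_tree):
    trees = [gene("(g1_A,g1_B);")]
    profile = duplication_ratios(trees, abc_species_tree)
    c = next(n for n in abc_species_tree.postorder() if n.label == "C")
    assert profile.ratio(c) is None
    frame = profile.to_frame()
    assert frame.loc[frame["node"] == "C", "ratio"].isna().all()


def test_expansion_cap_limits_per_tree_contribution(abc_species_tree):
    burst = gene("(((g1_A,g2_A),(g3_A,g4_A)),g1_B);")  # 3 dups at leaf A
    profile_uncapped = duplication_ratios([burst], abc_species_tree)
    profile_capped = duplication_ratios([burst], abc_species_tree,
                                        expansion_cap=1)
    a = next(n for n in abc_species_tree.postorder() if n.label == "A")
    assert profile_uncapped.counts[id(a)] == 3
    assert profile_capped.counts[id(a)] == 1


# ---------------------------------------------------------------------------
# homology relations
# ---------------------------------------------------------------------------

def test_one_to_one_orthologs():
    events = annotate_events(gene("((g1_A,g1_B),g1_C);"))
    rel = extract_relations(events)
    assert ("g1_A", "g1_B") in rel.one_to_one_pairs()
    assert rel.paralog_pairs() == set()


def test_many_to_one_orthologs_and_paralogs():
    events = annotate_events(gene("((g1_A,g2_A),g1_B);"))
    rel = extract_relations(events)
    assert rel.paralog_pairs() == {("g1_A", "g2_A")}
    kinds = dict(zip(map(tuple, rel.orthologs[["gene_a", "gene_b"]].values),
                     rel.orthologs["kind"]))
    assert kinds[("g1_A", "g1_B")] in ("many-to-one", "one-to-many")
    assert kinds[("g1_B", "g2_A")] in ("many-to-one", "one-to-many")


def test_single_species_tree_has_no_orthologs():
    events = annotate_events(gene("((g1_A,g2_A),g3_A);"))
    rel = extract_relations(events)
    assert rel.ortholog_pairs() == set()
    assert len(rel.paralog_pairs()) == 3


# ---------------------------------------------------------------------------
# gains and losses
# ---------------------------------------------------------------------------

def test_universal_presence_gains_at_root(abcd_species_tree):
    gl = infer_gain_loss({"og": {"A", "B", "C", "D"}}, abcd_species_tree)
    assert gl.gains["og"] is abcd_species_tree.root
    assert gl.losses["og"] == []


def test_single_missing_leaf_is_one_loss(abcd_species_tree):
    gl = infer_gain_loss({"og": {"A", "B", "C"}}, abcd_species_tree)
    assert gl.gains["og"] is abcd_species_tree.root
    assert [n.label for n in gl.losses["og"]] == ["D"]


def test_two_scattered_losses(abcd_species_tree):
    gl = infer_gain_loss({"og": {"A", "C"}}, abcd_species_tree)
    assert sorted(n.label for n in gl.losses["og"]) == ["B", "D"]


def test_gain_below_root_when_presence_is_cladewise(abcd_species_tree):
    gl = infer_gain_loss({"og": {"A", "B"}}, abcd_species_tree)
    assert clade_name(abcd_species_tree, gl.gains["og"]) == "A|B"
    assert gl.losses["og"] == []


def test_empty_presence_row_is_an_error(abcd_species_tree):
    with pytest.raises(DataError, match="og_bad"):
        infer_gain_loss({"og_bad": set()}, abcd_species_tree)


def test_dollo_minimality_against_exhaustive_enumeration(rng):
    """Inferred loss counts equal the exhaustive-search minimum over all
    loss-node subsets consistent with a single gain."""
    for seed in range(6):
        n = rng.randint(4, 8)
        sp = simulate_species_tree(n, seed=seed)
        species = sorted(sp.species)
        patterns = []
        for _ in range(12):
            k = rng.randint(1, n)
            patterns.append(set(rng.sample(species, k)))
        gl = infer_gain_loss({f"og{i}": p for i, p in enumerate(patterns)},
                             sp)
        for i, p in enumerate(patterns):
            assert len(gl.losses[f"og{i}"]) == dollo_min_losses(p, sp)
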