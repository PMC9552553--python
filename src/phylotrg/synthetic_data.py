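"""Synthetic inputs with known ground truth, plus packaged fixtures.

The simulators generate the statistical structure the pipeline assumes —
gene families evolving by duplication and loss along a species tree with an
exact event log, multi-tool orthology calls with configurable per-tool
error, and unimodal developmental expression time courses with an exactly
planted fraction of high-peak genes — so that every stage of the analysis
is testable without any external download.

Two small reference fixtures are packaged as code: the 15-species proteome
panel (mnemonic, NCBI taxid, species, source) with a literature-consistent
topology, and the 14-gene evidence table (RBBH partner, phylome tree
presence, ontology terms).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .phylo_io import GeneTree, SpeciesTree, TreeNode
from .reconciliation import annotate_events, extract_relations
from .trg_pipeline import evidence_report

__all__ = [
    "TIMEPOINTS",
    "SimulatedFamily",
    "SyntheticStudy",
    "simulate_species_tree",
    "simulate_family",
    "simulate_calls",
    "simulate_expression",
    "simulate_study",
    "table1_species",
    "table1_species_tree",
    "table2_fixture",
    "table2_report",
]

#: developmental sampling grid, hours post-fertilization
TIMEPOINTS: tuple[float, ...] = (0, 10, 18, 24, 40, 48, 56, 64, 72)


def _rng(seed) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def _insert_positions(top, leaf):
    yield (top, leaf)
    if isinstance(top, tuple):
        left, right = top
        for t in _insert_positions(left, leaf):
            yield (t, right)
        for t in _insert_positions(right, leaf):
            yield (left, t)


def simulate_species_tree(n_taxa: int, seed=0,
                          labels: Sequence[str] | None = None) -> SpeciesTree:
    """Random rooted binary species tree, uniform over labeled topologies.

    Leaves are inserted sequentially at a uniformly chosen attachment
    position; every rooted topology on ``k+1`` leaves arises from exactly
    one (topology, position) pair on ``k`` leaves, so the draw is uniform
    over the (2n-3)!! topologies.  Reproducible given ``seed``.
    """
    if n_taxa < 3:
        raise ConfigError("n_taxa must be at least 3")
    rng = _rng(seed)
    if labels is None:
        labels = [f"S{i + 1}" for i in range(n_taxa)]
    top = labels[0]
    for leaf in labels[1:]:
        options = list(_insert_positions(top, leaf))
        top = options[rng.randrange(len(options))]

    def build(t) -> TreeNode:
        if isinstance(t, tuple):
            node = TreeNode()
            node.add_child(build(t[0]))
            node.add_child(build(t[1]))
            return node
        return TreeNode(label=t)

    return SpeciesTree(build(top))


# ---------------------------------------------------------------------------
# Duplication–loss families
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFamily:
    """One gene family evolved along a species tree with its event log.

    ``dup_counts``/``loss_counts`` are keyed by ``id(species_node)`` and
    record every simulated event on the branch subtending that node,
    including the origin branch above the root.  With loss rate 0 every
    event is observable in the gene tree.
    """
    tree: GeneTree
    sp_tree: SpeciesTree
    dup_counts: dict[int, int]
    loss_counts: dict[int, int]
    dup_prob: float
    loss_prob: float
    seed: int | None
    n_redraws: int = 0

    @property
    def total_duplications(self) -> int:
        return sum(self.dup_counts.values())


def simulate_family(sp_tree: SpeciesTree, dup_prob: float, loss_prob: float,
                    seed=0, family_id: str = "fam") -> SimulatedFamily:
    """Evolve one ancestral gene along the species tree.

    On each branch (including the origin branch above the root) every
    incoming gene copy is first lost with probability ``loss_prob``; a
    surviving copy duplicates at most once with probability ``dup_prob``,
    and both daughter copies reach the end of the branch.  A family losing
    all copies is redrawn (the redraw count is reported).
    """
    if not (0 <= dup_prob < 1) or not (0 <= loss_prob < 1):
        raise ConfigError("dup_prob and loss_prob must be in [0, 1)")
    rng = _rng(seed)
    counter = [0]

    def attempt():
        dup_counts: dict[int, int] = {}
        loss_counts: dict[int, int] = {}

        def at_node(sp_node: TreeNode) -> TreeNode | None:
            # a surviving copy sitting at sp_node
            if sp_node.is_leaf:
                counter[0] += 1
                leaf = TreeNode(label=f"{family_id}.g{counter[0]}"
                                      f"_{sp_node.label}")
                leaf.species = sp_node.label
                return leaf
            kids = [sub for child in sp_node.children
                    if (sub := enter_branch(child)) is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = TreeNode()
            for k in kids:
                node.add_child(k)
            return node

        def enter_branch(sp_node: TreeNode) -> TreeNode | None:
            if rng.random() < loss_prob:
                loss_counts[id(sp_node)] = loss_counts.get(id(sp_node), 0) + 1
                return None
            if rng.random() < dup_prob:
                dup_counts[id(sp_node)] = dup_counts.get(id(sp_node), 0) + 1
                a, b = at_node(sp_node), at_node(sp_node)
                if a is not None and b is not None:
                    node = TreeNode()
                    node.add_child(a)
                    node.add_child(b)
                    return node
                return a if a is not None else b
            return at_node(sp_node)

        root = enter_branch(sp_tree.root)
        return root, dup_counts, loss_counts

    redraws = 0
    while True:
        root, dups, losses = attempt()
        if root is not None and not root.is_leaf:
            break
        if root is not None:  # single surviving leaf: keep (2-leaf min not required)
            break
        redraws += 1
        if redraws > 10_000:
            raise DataError("family went extinct in 10,000 consecutive "
                            "draws; lower loss_prob")
    tree = GeneTree(root, seed_sequence_id=None)
    tree.explicitly_rooted = True
    return SimulatedFamily(tree, sp_tree, dups, losses, dup_prob, loss_prob,
                           seed if isinstance(seed, int) else None, redraws)


# ---------------------------------------------------------------------------
# Orthology calls with planted error
# ---------------------------------------------------------------------------

def simulate_calls(families: Iterable[SimulatedFamily],
                   tools: Sequence[str], fn_rate: float = 0.0,
                   fp_rate: float = 0.0, seed=0) -> pd.DataFrame:
    """Per-tool one-to-one orthology calls derived from the true trees.

    Every true one-to-one ortholog pair (species-overlap speciation MRCA,
    single copy on each side) is emitted once per tool and independently
    dropped with probability ``fn_rate``; spurious cross-species calls are
    added per gene and tool with probability ``fp_rate``.
    """
    if not (0 <= fn_rate < 1) or not (0 <= fp_rate < 1):
        raise ConfigError("fn_rate and fp_rate must be in [0, 1)")
    rng = _rng(seed)
    rows = []
    all_species: set[str] = set()
    all_genes: list[tuple[str, str]] = []  # (gene, species)
    pairs: list[tuple[str, str, str, str]] = []
    for fam in families:
        events = annotate_events(fam.tree)
        relations = extract_relations(events)
        leaves = {l.label: l.species for l in fam.tree.leaves()}
        all_species.update(leaves.values())
        all_genes.extend(leaves.items())
        for a, b in sorted(relations.one_to_one_pairs()):
            pairs.append((a, leaves[a], b, leaves[b]))
    for tool in tools:
        for a, sp_a, b, sp_b in pairs:
            if rng.random() < fn_rate:
                continue
            rows.append((a, tool, sp_b, b, True))
            rows.append((b, tool, sp_a, a, True))
        if fp_rate:
            species = sorted(all_species)
            for gene, sp in all_genes:
                if rng.random() < fp_rate:
                    target_sp = species[rng.randrange(len(species))]
                    rows.append((gene, tool, target_sp,
                                 f"spurious.{gene}.{target_sp}", False))
    return pd.DataFrame(rows, columns=["gene", "tool", "target_species",
                                       "target_gene", "one_to_one"])


# ---------------------------------------------------------------------------
# Expression time courses
# ---------------------------------------------------------------------------

def simulate_expression(genes: Sequence[str],
                        timepoints: Sequence[float] = TIMEPOINTS,
                        peak_fraction: float = 0.1,
                        high_genes: Iterable[str] | None = None,
                        threshold: float = 50.0,
                        peak_window: tuple[float, float] = (18.0, 24.0),
                        spread: float = 8.0, seed=0) -> pd.DataFrame:
    """Unimodal TPM time courses with an exactly planted high-peak set.

    Each gene follows a Gaussian-shaped course peaking inside
    ``peak_window`` (hours), rescaled so its maximum over the sampling grid
    equals the drawn peak value exactly.  ``high_genes`` (or, when None, a
    seeded sample of ``round(peak_fraction * n)`` genes) get peaks strictly
    above ``threshold``; all other genes stay at or below it.  The planting
    is deterministic: the high count is exact, not sampled.
    """
    if not 0 <= peak_fraction <= 1:
        raise ConfigError("peak_fraction must be in [0, 1]")
    rng = _rng(seed)
    genes = list(genes)
    if high_genes is None:
        n_high = round(peak_fraction * len(genes))
        high = set(rng.sample(genes, n_high)) if n_high else set()
    else:
        high = set(high_genes)
        unknown = high - set(genes)
        if unknown:
            raise DataError(f"high_genes not in gene list: "
                            f"{sorted(unknown)[:5]}")
    rows = {}
    for gene in genes:
        t0 = rng.uniform(*peak_window)
        shape = [pow(2.718281828459045,
                     -((t - t0) ** 2) / (2 * spread ** 2))
                 for t in timepoints]
        mx = max(shape)
        if gene in high:
            peak = rng.uniform(threshold * 1.02, threshold * 20)
        else:
            peak = rng.uniform(0.0, threshold)
        rows[gene] = [peak * s / mx for s in shape]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[float(t) for t in timepoints])
    df.index.name = "gene"
    return df


# ---------------------------------------------------------------------------
# A full synthetic study for the cascade
# ---------------------------------------------------------------------------

STUDY_INGROUP_TARGETS = ("ACAPL", "ANNJA")
STUDY_OUTGROUP = ("HUMAN", "MOUSE", "DROME", "CAEEL", "DANRE",
                  "XENTR", "ARATH", "YEAST", "SCHPO", "RATNO")
STUDY_TOOLS = ("InParanoid", "ProteinOrtho", "SwiftOrtho", "FastOrtho",
               "OMA", "OrthoFinder")
#: OMA lacks the Asteroidea and Crinoidea comparisons, so only five tools
#: are required for the two non-focal echinoderms.
STUDY_TOOL_REGISTRY = {
    "ACAPL": tuple(t for t in STUDY_TOOLS if t != "OMA"),
    "ANNJA": tuple(t for t in STUDY_TOOLS if t != "OMA"),
}
STUDY_RBBH_PROTEOMES = ("NEMVE", "BRAFL", "CIOIN")


@dataclass
class SyntheticStudy:
    """All cascade inputs plus the planted ground truth."""
    calls: pd.DataFrame
    annotations: pd.DataFrame
    isoforms: pd.DataFrame
    expression: pd.DataFrame
    te_domains: frozenset[str]
    ingroup: tuple[str, ...]
    outgroup: tuple[str, ...]
    tool_registry: Mapping[str, Sequence[str]]
    rbbh: dict[str, list[tuple[str, str]]]
    tree_registry: dict[str, bool]
    tree_ids: dict[str, str]
    planted_trgs: frozenset[str]
    seed: int

    def cascade_kwargs(self) -> dict:
        return dict(calls=self.calls, ingroup=self.ingroup,
                    outgroup=self.outgroup, annotations=self.annotations,
                    isoforms=self.isoforms, expression=self.expression,
                    te_domains=self.te_domains,
                    tool_registry=self.tool_registry, rbbh=self.rbbh,
                    tree_registry=self.tree_registry, tree_ids=self.tree_ids,
                    proteome_priority=list(STUDY_RBBH_PROTEOMES))


def simulate_study(seed: int = 0, n_trgs: int = 14, n_expression_fail: int = 17,
                   n_annotated: int = 100, n_te: int = 8, n_extra_isoforms: int = 6,
                   n_outgroup_hit: int = 40, n_nonconsensus: int = 15,
                   n_rbbh: int = 7, n_with_tree: int = 8,
                   fn_rate: float = 0.0, fp_rate: float = 0.0,
                   min_peak: float = 50.0) -> SyntheticStudy:
    """Build a full synthetic study with a planted TRG set.

    The default category sizes mirror the reference filtering trace: 145
    candidates survive consensus + outgroup exclusion (14 planted TRGs,
    ``n_expression_fail`` = 17 that fail only the expression peak, and
    ``n_annotated + n_te + n_extra_isoforms`` = 114 removed by the
    annotation and isoform stages), narrowing to 31 and finally to the 14
    planted genes.  ``fn_rate`` drops true ingroup calls per tool and gene;
    ``fp_rate`` adds spurious outgroup calls; at zero error the cascade
    returns exactly the planted set.
    """
    rng = random.Random(seed)
    ingroup = STUDY_INGROUP_TARGETS
    outgroup = STUDY_OUTGROUP
    registry = {sp: tuple(tools) for sp, tools in STUDY_TOOL_REGISTRY.items()}

    def gene_ids(prefix: str, n: int) -> list[str]:
        return [f"{prefix}{i:04d}" for i in range(n)]

    trgs = gene_ids("TRG", n_trgs)
    lowexpr = gene_ids("LOW", n_expression_fail)
    annotated = gene_ids("ANN", n_annotated)
    te_genes = gene_ids("TEG", n_te)
    outhit = gene_ids("OUT", n_outgroup_hit)
    noncons = gene_ids("NCS", n_nonconsensus)
    # extra (shorter) isoform models of unannotated surviving genes
    iso_parents = (trgs + lowexpr)[:n_extra_isoforms]
    extra_iso = [f"{g}.iso2" for g in iso_parents]

    consensus_members = trgs + lowexpr + annotated + te_genes + extra_iso + outhit
    universe = consensus_members + noncons

    # --- orthology calls -------------------------------------------------
    rows = []
    for gene in universe:
        drop_tool = None
        if gene in set(noncons):
            sp = ingroup[rng.randrange(len(ingroup))]
            tools = registry[sp]
            drop_tool = (sp, tools[rng.randrange(len(tools))])
        for sp in ingroup:
            for tool in registry[sp]:
                if drop_tool == (sp, tool):
                    continue
                if fn_rate and rng.random() < fn_rate:
                    continue
                rows.append((gene, tool, sp, f"{sp}.{gene}", True))
    for gene in outhit:
        tool = STUDY_TOOLS[rng.randrange(len(STUDY_TOOLS))]
        sp = outgroup[rng.randrange(len(outgroup))]
        rows.append((gene, tool, sp, f"{sp}.{gene}", False))
    if fp_rate:
        for gene in universe:
            for tool in STUDY_TOOLS:
                if rng.random() < fp_rate:
                    sp = outgroup[rng.randrange(len(outgroup))]
                    rows.append((gene, tool, sp, f"{sp}.sp.{gene}", False))
    calls = pd.DataFrame(rows, columns=["gene", "tool", "target_species",
                                        "target_gene", "one_to_one"])

    # --- annotations ------------------------------------------------------
    te_domain_ids = frozenset({"PF03221", "PF00078", "PF13456"})
    ann_rows = []
    for i, gene in enumerate(annotated):
        ann_rows.append({"gene": gene,
                         "go_terms": frozenset({f"GO:{7000000 + i:07d}"}),
                         "domains": frozenset()})
    for gene in te_genes:
        ann_rows.append({"gene": gene, "go_terms": frozenset(),
                         "domains": frozenset({sorted(te_domain_ids)[0]})})
    annotations = pd.DataFrame(ann_rows,
                               columns=["gene", "go_terms", "domains"])

    # --- isoforms ---------------------------------------------------------
    iso_rows = [{"gene": g, "isoform": g, "length": 300 + 10 * i}
                for i, g in enumerate(consensus_members + noncons)
                if not g.endswith(".iso2")]
    for parent, iso in zip(iso_parents, extra_iso):
        parent_len = next(r["length"] for r in iso_rows
                          if r["isoform"] == parent)
        iso_rows.append({"gene": parent, "isoform": iso,
                         "length": parent_len - 50})
    isoforms = pd.DataFrame(iso_rows, columns=["gene", "isoform", "length"])

    # --- expression -------------------------------------------------------
    # high peaks: the planted TRGs plus a few unrelated genes, so the >50
    # decile is not a degenerate give-away of the answer
    n_decoy_high = max(0, round(0.1 * len(universe)) - n_trgs)
    decoy_pool = [g for g in annotated + te_genes + outhit + noncons]
    decoys = rng.sample(decoy_pool, min(n_decoy_high, len(decoy_pool)))
    expression = simulate_expression(
        universe, peak_fraction=0.0, high_genes=set(trgs) | set(decoys),
        threshold=min_peak, seed=rng.randrange(2 ** 31))

    # --- RBBH and trees ---------------------------------------------------
    rbbh: dict[str, list[tuple[str, str]]] = {p: []
                                              for p in STUDY_RBBH_PROTEOMES}
    with_rbbh = trgs[:n_rbbh]
    for i, gene in enumerate(with_rbbh):
        proteome = STUDY_RBBH_PROTEOMES[i % len(STUDY_RBBH_PROTEOMES)]
        rbbh[proteome].append((gene, f"{proteome}.partner.{gene}"))
    without_rbbh = [g for g in trgs if g not in set(with_rbbh)]
    # trees: cover all but one of the RBBH-less genes first, then top up
    # from the RBBH-positive genes, leaving exactly one zero-evidence gene
    treed = without_rbbh[:max(0, len(without_rbbh) - 1)]
    treed += with_rbbh[:max(0, n_with_tree - len(treed))]
    tree_registry = {g: True for g in treed}
    tree_ids = {g: f"PhySIM{i:05d}_STRPU" for i, g in enumerate(sorted(treed))}

    return SyntheticStudy(
        calls=calls, annotations=annotations, isoforms=isoforms,
        expression=expression, te_domains=te_domain_ids,
        ingroup=ingroup, outgroup=outgroup, tool_registry=registry,
        rbbh=rbbh, tree_registry=tree_registry, tree_ids=tree_ids,
        planted_trgs=frozenset(trgs), seed=seed)


# ---------------------------------------------------------------------------
# Packaged reference fixtures
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    ("STRPU", 7668, "Strongylocentrotus purpuratus", "Echinobase"),
    ("ACAPL", 133434, "Acanthaster planci", "OIST Marine genomics"),
    ("1529436", 1529436, "Anneissia japonica", "NCBI, PRJNA615663"),
    ("CIOIN", 7719, "Ciona intestinalis", "Quest For Orthologs 2008"),
    ("NEMVE", 45351, "Nematostella vectensis", "Quest For Orthologs 2020"),
    ("BRAFL", 7739, "Branchiostoma floridae", "OIST Marine genomics"),
    ("AMPQE", 400682, "Amphimedon queenslandica", "Ensembl Metazoa"),
    ("CRAVI", 6565, "Crassostrea virginica", "NCBI, PRJNA376014"),
    ("283909", 283909, "Capitella teleta", "NCBI, PRJNA175705"),
    ("CAEEL", 6239, "Caenorhabditis elegans", "Quest For Orthologs, 2020"),
    ("XENTR", 8364, "Xenopus tropicalis", "Xenbase"),
    ("CHICK", 9031, "Gallus gallus", "Quest For Orthologs, 2020"),
    ("DROME", 7227, "Drosophila melanogaster", "Quest For Orthologs, 2020"),
    ("SACKO", 10224, "Saccoglossus kowalevskii", "OIST Marine genomics"),
    ("HUMAN", 9606, "Homo sapiens", "Quest For Orthologs, 2020"),
]

#: literature-consistent topology over the 15 proteome mnemonics
_TABLE1_NEWICK = (
    "(AMPQE,(NEMVE,(((CAEEL,DROME),(CRAVI,283909)),"
    "((BRAFL,(CIOIN,(XENTR,(CHICK,HUMAN)))),"
    "(SACKO,(1529436,(ACAPL,STRPU)))))));"
)


def table1_species() -> pd.DataFrame:
    """The 15-species proteome panel (mnemonic, NCBI taxid, name, source)."""
    return pd.DataFrame(_TABLE1_ROWS, columns=["mnemonic", "ncbi_taxid",
                                               "species", "source"])


def table1_species_tree() -> SpeciesTree:
    """A rooted species tree over the panel's 15 mnemonics."""
    from .phylo_io import read_newick
    return read_newick(_TABLE1_NEWICK, kind="species")


# gene, RBBH partner (None = N/A), phylome ID, has tree, ontology terms
_TABLE2_ROWS = [
    ("LOC100890987", None, "Phy00E9VCL_STRPU", True, ()),
    ("LOC100891212", None, "Phy00E9NDK_STRPU", True, ()),
    ("LOC577463", None, "Phy000VU63_STRPU", False, ("GO:0005515",)),
    ("LOC577943", None, "Phy00E9SJD_STRPU", True, ()),
    ("LOC578009", None, "Phy000VM39_STRPU", False, ()),
    ("LOC578017", None, "Phy00E9SMM_STRPU", True, ()),
    ("LOC582352", None, "Phy00E9ZEJ_STRPU", True, ()),
    ("LOC762881", "C3YW32_BRAFL", "Phy000VNKZ_STRPU", False, ()),
    ("LOC100893267_iso_X1", "C3YI62_BRAFL", "Phy00E9SFI_STRPU", True,
     ("GO:0031262", "GO:0051315")),
    ("LOC100888903", "A7S6U8_NEMVE", "Phy00EA5U1_STRPU", True, ()),
    ("LOC100891350", "A7SDT1_NEMVE", "Phy00EA8QT_STRPU", False,
     ("GO:0005509",)),
    ("LOC580808", "A7S7R1_NEMVE", "Phy0037CV2_STRPU", False, ()),
    ("LOC577313", "F6REZ6_CIOIN", "Phy00EAAOU_STRPU", True, ()),
    ("LOC578221", "C3ZA97_BRAFL", "Phy000VYP2_STRPU", False, ()),
]


def table2_fixture() -> pd.DataFrame:
    """The packaged 14-gene evidence table.

    Columns: gene, rbbh (None when absent), phylome_id, has_tree (False for
    IDs that have no corresponding tree) and ontology (frozenset of GO
    terms, empty when unannotated).
    """
    return pd.DataFrame(
        [{"gene": g, "rbbh": r, "phylome_id": p, "has_tree": t,
          "ontology": frozenset(o)} for g, r, p, t, o in _TABLE2_ROWS],
        columns=["gene", "rbbh", "phylome_id", "has_tree", "ontology"])


def table2_report() -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the evidence report on the packaged gene-set fixture.

    RBBH partners are grouped by target proteome (the mnemonic suffix of
    the partner ID) with the priority order NEMVE, BRAFL, CIOIN.
    """
    fixture = table2_fixture()
    rbbh: dict[str, list[tuple[str, str]]] = {}
    for _, row in fixture.iterrows():
        if row["rbbh"] is not None:
            proteome = row["rbbh"].rsplit("_", 1)[1]
            rbbh.setdefault(proteome, []).append((row["gene"], row["rbbh"]))
    annotations = pd.DataFrame({
        "gene": fixture["gene"],
        "go_terms": fixture["ontology"],
        "domains": [frozenset()] * len(fixture),
    })
    tree_registry = dict(zip(fixture["gene"], fixture["has_tree"]))
    tree_ids = dict(zip(fixture["gene"], fixture["phylome_id"]))
    return evidence_report(
        fixture["gene"], rbbh, annotations, tree_registry, tree_ids,
        proteome_priority=["NEMVE", "BRAFL", "CIOIN"])
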