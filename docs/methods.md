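# Methods

This note records the models implemented in `phylotrg`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that matter when comparing runs.

## Species-overlap reconciliation

Event calling traverses a rooted gene tree in postorder. For a binary node
with daughter species sets $L$ and $R$ the overlap score is
$|L \cap R| / |L \cup R| \in [0, 1]$; the node is a duplication iff the
score strictly exceeds `overlap_cutoff`. The default cutoff of 0.0
reproduces the plain rule — any species present on both sides implies a
duplication — and raising it trades sensitivity for specificity; the count
of duplication calls is non-increasing in the cutoff (tested). A
multifurcating node is scored over all pairs of child partitions and uses
the maximum pairwise score, which is the conservative generalization of
the binary rule: any overlapping pair suffices for a duplication.

Event calling requires a rooted tree. Trees whose root has more than two
children are refused unless explicitly marked as rooted, because the
species-overlap call at the root changes with root placement. Rooting
strategies provided: `none`, `seed-farthest` (root on the edge to the leaf
farthest from the phylome seed, topological distance when branch lengths
are absent), `midpoint`, and `min-duplications` (exhaustive enumeration of
all $2n-3$ edge rootings, choosing the fewest species-overlap
duplications; ties break on the lexicographically smallest
children-sorted newick, so results are deterministic).

## Duplication mapping and ratios

A duplication node maps to the species-tree MRCA of the union of its
daughter species sets. The per-node duplication ratio divides mapped
duplications by the number of gene trees *containing* the node.
Containment is a genuine modelling choice with no single canonical
definition; the default — a tree contains an internal node when its
species intersect **both** daughter clades (for a leaf: include the
species) — counts exactly the trees in which a duplication *could* map to
that node, so a ratio of 1 genuinely means one duplication per eligible
gene. The looser alternative (`containment="clade"`, intersecting the
node's clade at all) is available for sensitivity analysis. Nodes
contained by no tree get an undefined ratio (`None`/NaN), never 0: absence
of evidence is reported as such.

Large family expansions (tandem arrays and similar) can dominate per-node
counts. `expansion_cap` bounds the duplications a single gene tree may
contribute to one node. The cap is off by default and the choice of value
(3 is a reasonable working setting) is deliberately exposed because no
principled default exists; analyses that quote "rates without large
expansions" should state their cap.

## Gains and losses

Each orthologous family is assumed to arise exactly once (Dollo): the gain
sits at the MRCA of the species possessing the family, and losses are
placed at the highest nodes below the gain whose whole clade lacks it.
This placement attains the minimum possible number of losses for a
single-gain model and avoids double-counting descendants of a lost clade
(verified against exhaustive enumeration of loss-node subsets on up to 8
species).

## Duplication-minimizing species trees

A candidate topology is scored by the classical LCA-reconciliation
duplication cost: each gene-tree node maps to the species-tree MRCA of its
leaf species, and a node is a duplication when it maps to the same
species-tree node as one of its children. The search minimizes the summed
cost over the gene-tree collection — exhaustively for up to 7 taxa
($(2n-3)!!$ rooted topologies), or by NNI hill-climbing with a
deterministic caterpillar start plus seeded random restarts (5 by
default) and lexicographic tie-breaking above that.

Two rooting policies exist for the gene trees being reconciled, and the
choice matters. `fixed` (default) reconciles each tree as given; since
phylome gene trees are rooted upstream of this package, keeping their
roots preserves information and, in particular, makes the *root* of the
species tree identifiable. `optimal` re-roots every gene tree at its
cost-minimizing edge per candidate; this is the right choice for genuinely
unrooted input but makes the score invariant to the candidate's own root
placement, so the returned root is then an arbitrary (deterministic)
choice among tied rooted variants of the same unrooted topology.

Single-copy family selection implements the near-universal rule (at most
one member per species, present in at least *m* of *t* species; the
packaged study panel uses 14 of 15). Concatenation produces a taxa ×
positions supermatrix with 0-based half-open partition coordinates and
fully gap-masked rows for taxa missing a family; downstream ML inference
is intentionally out of scope — the supermatrix is written for external
tools.

## The filtering cascade

Stage order is fixed: consensus → outgroup exclusion → unannotated →
longest isoform → expression → RBBH/evidence report. Every stage maps a
gene set to a subset and is logged in a `FilterTrace` (counts are
validated to chain and to be non-increasing). Conventions worth noting:

- **Consensus** requires a one-to-one call to *every* ingroup species by
  *every* tool registered for that species pair. The registry is per pair
  because real tool panels are ragged (in the packaged study
  configuration, one of six tools lacks the two non-focal echinoderm
  comparisons, so five tools are required there).
- **Outgroup exclusion** treats *any* call by *any* tool to an outgroup
  species as disqualifying homology evidence, whether or not it is
  one-to-one. This is the aggressive reading; it errs toward excluding
  borderline candidates rather than admitting false TRGs.
- **Hit filtering**: e-value strictly `< 1e-5`; coverage is a single hit
  record's query span `(qend − qstart + 1) / qlen ≥ 0.5` — no chaining of
  multiple HSPs; the 150-hit cap keeps the smallest e-values with ties
  broken by bit score descending then subject ID. Hit tables use 1-based
  inclusive coordinates at the file boundary (the tabular dialect);
  everything internal is 0-based half-open.
- **Expression**: peak TPM strictly `> 50`. The observation that such a
  threshold selects roughly the top decile of a developmental dataset is
  diagnostic, not a second rule: the threshold is the filter.
- **Isoform collapse** keeps the longest model per gene, ties broken by
  isoform ID ascending. This stage commutes with the annotation filter
  (tested), so their relative order does not change the final set.
- **RBBH** at the relaxed threshold `1e-7`: a pair requires mutual unique
  best hits; a query whose top two hits tie on both e-value and bit score
  is ambiguous and produces no pair. When a gene has RBBH partners in
  several proteomes the reported partner follows a declared proteome
  priority and all partners are recorded.
- **Evidence report** summary counts: total, with RBBH, ontology-absent,
  with/without phylome tree, and zero-evidence (no RBBH, no ontology, no
  tree).

## Enrichment and selection summaries

Term enrichment uses the hypergeometric distribution on the 2×2 table of
study/background × with/without term; one-sided over-representation is the
default, two-sided (doubled smaller tail, capped at 1) by option.
P-values are adjusted with Benjamini–Hochberg FDR across the tested terms;
BH is the conventional default for exploratory GO screens and the
procedure is recorded in the output so alternatives can be substituted.
Selection summaries count sites with posterior probability **≥** 0.95
(inclusive, the conventional reading of a 0.95 credibility cutoff) for
each direction and report percentages to one decimal; a gene with no sites
gets undefined percentages.

## Synthetic data: what it emulates, and what it does not

`simulate_family` evolves one ancestral gene along a species tree with
branch-discrete events: on each branch (including an origin branch above
the root) every incoming copy is lost with probability μ, else duplicates
at most once with probability λ, both daughters surviving to the branch
end. Discrete per-branch Bernoulli events were chosen over a
continuous-time birth–death process because they give exact event
bookkeeping and closed-form expectations for tests (mean duplications per
family is Σ_branches (1+λ)^(ancestor branches) · λ at μ = 0, verified by
Monte Carlo). The cost is realism: no multiple duplications of the same
copy within a branch, no rate heterogeneity across branches or families,
and no sequence evolution at all — trees and events only.

`simulate_calls` emits the true one-to-one ortholog pairs per tool,
dropping each with a per-tool false-negative rate and adding spurious
calls at a false-positive rate. Errors are independent across tools and
pairs; real orthology tools fail in correlated ways (shared BLAST
substrate, similar clustering heuristics), so passing recovery tests here
bounds only the independent-error regime.

`simulate_expression` draws Gaussian-shaped time courses on the
nine-point developmental grid (0–72 h post-fertilization) peaking between
18 and 24 h, rescaled so each gene's grid maximum equals its drawn peak
exactly; the high-peak gene set is planted deterministically (exact count,
not a sample), which keeps cascade tests non-flaky. Real developmental
profiles are of course not unimodal Gaussians; the generator reproduces
only the feature the filter reads — the peak value.

`simulate_study` assembles a full cascade input with category sizes
defaulting to the packaged study's structure: 200 gene models, 145
surviving consensus + outgroup exclusion, 31 after the annotation and
isoform stages, 14 planted TRGs passing everything, 7 with RBBH partners
and 8 with phylome trees, leaving exactly one zero-evidence gene. Passing
the planted-recovery tests shows the bookkeeping of every filter is
correct; it says nothing about the biological error rates of the upstream
tools on real proteomes.

## Numerical and formatting conventions

- Newick: quoted labels supported; NHX comment blocks tolerated and
  ignored; a bare numeric internal label is read as support; branch
  lengths are optional everywhere and written back with full float
  precision (round-trip to 1e-9 is tested).
- Leaf-to-species mapping defaults to "suffix after the final
  underscore"; an explicit lookup table or custom regex overrides it.
  Unmappable leaves are an error, never dropped.
- Upstream data releases sometimes list the 40 h timepoint twice; this is
  treated as a typo: the expression schema uses nine unique timepoints, and duplicate
  column headers in input are an error.
- All simulators are pure functions of (parameters, seed); every
  stochastic default in tests and the acceptance script derives from one
  seed.
- Problem sizes in the test-suite properties (e.g. 500 simulated families
  for event recovery, 50 gene-tree collections for exhaustive-search
  optimality on up to 6 taxa, 200 random enrichment tables) were chosen as
  the smallest sizes at which the properties are exercised across the full
  configuration space.

## Known limitations

- Reconciliation is parsimony-style only: no probabilistic duplication–
  loss models, no transfers, no branch-length-aware event dating.
- The species-overlap rule over-calls duplications when gene trees contain
  topological error; the overlap cutoff mitigates but does not model this.
- The NNI search is a local optimizer; restarts reduce but do not
  eliminate the risk of local optima on adversarial collections.
- `exclude_outgroup_homologs` consumes orthology *call tables*; if
  upstream tools emit homology evidence that never reaches the call table,
  the cascade cannot see it.
- The enrichment module assumes exchangeable genes (no gene-length or
  expression bias correction).
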