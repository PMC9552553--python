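"""Taxonomically-restricted-gene discovery cascade.

Candidate lineage-restricted genes are recovered by intersecting one-to-one
orthology calls from several prediction tools across the ingroup species,
excluding anything any tool links to an outgroup species, keeping only
unannotated models (no GO terms, no transposable-element domains), collapsing
isoforms to the longest model, and requiring a developmental expression peak
above a TPM threshold.  Survivors are then characterized by relaxed
reciprocal-best-hit searches against reference proteomes and by presence of
a phylome gene tree, yielding a per-gene evidence report.

Every stage consumes and returns plain gene sets, and :class:`FilterTrace`
records the input/output counts and removed IDs per stage so a run is fully
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .phylo_io import HitTable

__all__ = [
    "FilterTrace",
    "CascadeResult",
    "filter_hits",
    "consensus_echinoderm",
    "exclude_outgroup_homologs",
    "unannotated_only",
    "longest_isoform",
    "expression_filter",
    "reciprocal_best_hits",
    "evidence_report",
    "run_cascade",
]


# ---------------------------------------------------------------------------
# Hit filtering
# ---------------------------------------------------------------------------

def filter_hits(hits: HitTable, max_evalue: float = 1e-5,
                min_coverage: float = 0.5, max_hits: int = 150) -> HitTable:
    """Retain significant hits: e-value strictly below ``max_evalue`` and a
    single contiguous aligned query segment covering at least
    ``min_coverage`` of the query, then cap each query at its ``max_hits``
    closest hits (smallest e-value; ties by bit score descending, then
    subject ID)."""
    df = hits.df
    if len(df) == 0:
        return HitTable(df.copy(), hits.query_lengths)
    unknown = sorted(set(df["qseqid"]) - set(hits.query_lengths))
    if unknown:
        raise DataError(
            f"queries without a registered length: {unknown[:5]}")
    qlen = df["qseqid"].map(hits.query_lengths)
    coverage = (df["qend"] - df["qstart"] + 1) / qlen
    keep = (df["evalue"] < max_evalue) & (coverage >= min_coverage)
    kept = df[keep]
    # per-query cap on the closest hits
    ranked = kept.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True], kind="mergesort")
    capped_idx = ranked.groupby("qseqid").head(max_hits).index
    out = df.loc[df.index.intersection(capped_idx)]  # preserve input order
    return HitTable(out.reset_index(drop=True), hits.query_lengths)


# ---------------------------------------------------------------------------
# Consensus orthology and outgroup exclusion
# ---------------------------------------------------------------------------

def _normalize_registry(tool_registry, ingroup: Iterable[str],
                        calls: pd.DataFrame):
    """Tool requirements per ingroup species.

    ``tool_registry`` may be a flat tool collection (required for every
    species), a mapping species → tools (mirroring, e.g., a tool missing for
    some comparisons), or None (every tool seen in the call table is
    required everywhere).
    """
    ingroup = set(ingroup)
    if tool_registry is None:
        tools = set(calls["tool"].unique())
        return {sp: tools for sp in ingroup}
    if isinstance(tool_registry, Mapping):
        missing = ingroup - set(tool_registry)
        if missing:
            raise ConfigError(
                f"tool registry lacks ingroup species: {sorted(missing)}")
        return {sp: set(tool_registry[sp]) for sp in ingroup}
    return {sp: set(tool_registry) for sp in ingroup}


def consensus_echinoderm(calls: pd.DataFrame, ingroup: Iterable[str],
                         tool_registry=None) -> set[str]:
    """Genes called one-to-one orthologous to *every* ingroup species by
    *every* tool registered for that species pair."""
    ingroup = set(ingroup)
    if not ingroup:
        raise ConfigError("ingroup species set is empty")
    registry = _normalize_registry(tool_registry, ingroup, calls)
    if any(not tools for tools in registry.values()):
        raise ConfigError("a species has an empty required-tool set")
    one2one = calls[calls["one_to_one"].astype(bool)]
    seen: set[tuple[str, str, str]] = set(zip(one2one["gene"],
                                              one2one["tool"],
                                              one2one["target_species"]))
    genes = set(calls["gene"].unique())
    out = set()
    for gene in genes:
        if all((gene, tool, sp) in seen
               for sp in ingroup for tool in registry[sp]):
            out.add(gene)
    return out


def exclude_outgroup_homologs(candidates: Iterable[str], calls: pd.DataFrame,
                              outgroup: Iterable[str]) -> set[str]:
    """Drop any candidate with at least one call — by any tool, one-to-one
    or not — to any outgroup species."""
    outgroup = set(outgroup)
    flagged = set(calls.loc[calls["target_species"].isin(outgroup), "gene"])
    return set(candidates) - flagged


# ---------------------------------------------------------------------------
# Annotation / isoform / expression filters
# ---------------------------------------------------------------------------

def unannotated_only(genes: Iterable[str], annotations: pd.DataFrame,
                     te_domains: Iterable[str] = frozenset()) -> set[str]:
    """Retain genes with an empty ontology set and no transposable-element
    domain; a gene absent from the annotation table counts as unannotated."""
    te_domains = frozenset(te_domains)
    ann = annotations.set_index("gene")
    out = set()
    for gene in genes:
        if gene in ann.index:
            row = ann.loc[gene]
            if row["go_terms"]:
                continue
            if te_domains and row["domains"] & te_domains:
                continue
        out.add(gene)
    return out


def longest_isoform(genes: Iterable[str], isoforms: pd.DataFrame
                    ) -> set[str]:
    """Collapse isoform models of the same gene to the single longest one
    (length ties broken by isoform ID ascending).

    ``genes`` holds isoform/model IDs; ``isoforms`` maps each model to its
    gene and length.  A model missing from the table is treated as the sole
    model of its own gene and kept.
    """
    genes = set(genes)
    table = isoforms[isoforms["isoform"].isin(genes)]
    keep = set(genes) - set(table["isoform"])  # unlisted: singleton models
    ranked = table.sort_values(["gene", "length", "isoform"],
                               ascending=[True, False, True],
                               kind="mergesort")
    keep |= set(ranked.groupby("gene").head(1)["isoform"])
    return keep


def expression_filter(genes: Iterable[str], expression: pd.DataFrame,
                      min_peak: float = 50.0) -> set[str]:
    """Retain genes whose maximal TPM across timepoints is strictly greater
    than ``min_peak``; a gene without an expression row counts as silent."""
    if len(expression) and (expression.values < 0).any():
        raise DataError("negative TPM in expression matrix")
    peaks = expression.max(axis=1)
    return {g for g in genes if g in peaks.index and peaks[g] > min_peak}


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hits(hits: HitTable, max_evalue: float) -> dict[str, str]:
    """Unique best subject per query; queries whose top two hits tie on
    (e-value, bit score) are ambiguous and yield no best hit."""
    df = hits.df[hits.df["evalue"] < max_evalue]
    best: dict[str, str] = {}
    for q, grp in df.groupby("qseqid"):
        ranked = grp.sort_values(["evalue", "bitscore", "sseqid"],
                                 ascending=[True, False, True],
                                 kind="mergesort")
        if len(ranked) > 1:
            a, b = ranked.iloc[0], ranked.iloc[1]
            if a["evalue"] == b["evalue"] and a["bitscore"] == b["bitscore"]:
                continue
        best[q] = ranked.iloc[0]["sseqid"]
    return best


def reciprocal_best_hits(hits_ab: HitTable, hits_ba: HitTable,
                         max_evalue: float = 1e-7) -> list[tuple[str, str]]:
    """Pairs (a, b) where b is a's unique best hit in proteome B and a is
    b's unique best hit in proteome A, both below ``max_evalue``; sorted for
    determinism."""
    best_ab = _best_hits(hits_ab, max_evalue)
    best_ba = _best_hits(hits_ba, max_evalue)
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Evidence report
# ---------------------------------------------------------------------------

def evidence_report(genes: Iterable[str],
                    rbbh: Mapping[str, Iterable[tuple[str, str]]],
                    annotations: pd.DataFrame,
                    tree_registry: Mapping[str, bool],
                    tree_ids: Mapping[str, str] | None = None,
                    proteome_priority: Sequence[str] | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene evidence table (the final gene-set report) plus summary
    counts.

    ``rbbh`` maps proteome name → RBBH pairs (gene, partner); when a gene
    has partners in several proteomes the reported partner follows
    ``proteome_priority`` (default: sorted proteome names) and all partners
    are recorded.  ``tree_registry`` flags genes with a phylome tree.

    Summary counts: total, with_rbbh, ontology_absent, with_tree,
    without_tree, no_evidence (neither RBBH, nor ontology, nor tree).
    """
    genes = sorted(set(genes))
    if proteome_priority is None:
        proteome_priority = sorted(rbbh)
    partner_by_gene: dict[str, dict[str, str]] = {}
    for proteome in rbbh:
        for a, b in rbbh[proteome]:
            partner_by_gene.setdefault(a, {})[proteome] = b
    ann = annotations.set_index("gene") if len(annotations) else None
    rows = []
    for gene in genes:
        partners = partner_by_gene.get(gene, {})
        partner = None
        for proteome in proteome_priority:
            if proteome in partners:
                partner = partners[proteome]
                break
        terms = frozenset()
        if ann is not None and gene in ann.index:
            terms = ann.loc[gene, "go_terms"]
        has_tree = bool(tree_registry.get(gene, False))
        rows.append({
            "gene": gene,
            "rbbh": partner,
            "rbbh_all": ";".join(f"{p}:{partners[p]}"
                                 for p in proteome_priority if p in partners)
                        or None,
            "tree_id": (tree_ids or {}).get(gene),
            "has_tree": has_tree,
            "ontology": ";".join(sorted(terms)) or None,
        })
    report = pd.DataFrame(rows, columns=["gene", "rbbh", "rbbh_all",
                                         "tree_id", "has_tree", "ontology"])
    summary = {
        "total": len(report),
        "with_rbbh": int(report["rbbh"].notna().sum()),
        "ontology_absent": int(report["ontology"].isna().sum()),
        "with_tree": int(report["has_tree"].sum()),
        "without_tree": int((~report["has_tree"]).sum()),
        "no_evidence": int((report["rbbh"].isna()
                            & report["ontology"].isna()
                            & ~report["has_tree"]).sum()),
    }
    return report, summary


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

class FilterTrace:
    """Ordered record of cascade stages with input/output counts and the
    IDs removed at each stage."""

    def __init__(self):
        self.stages: list[dict] = []

    def add(self, name: str, before: set[str], after: set[str]) -> None:
        if not after <= before:
            raise DataError(f"stage {name!r} produced genes outside its "
                            "input set")
        if self.stages and self.stages[-1]["n_out"] != len(before):
            raise DataError(f"stage {name!r} input count does not match the "
                            "previous stage output")
        self.stages.append({
            "stage": name,
            "n_in": len(before),
            "n_out": len(after),
            "removed": sorted(before - after),
        })

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s["stage"], s["n_in"], s["n_out"]) for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s["stage"], "n_in": s["n_in"], "n_out": s["n_out"],
              "n_removed": len(s["removed"])} for s in self.stages],
            columns=["stage", "n_in", "n_out", "n_removed"])


@dataclass
class CascadeResult:
    trace: FilterTrace
    final_genes: set[str]
    evidence: pd.DataFrame
    summary: dict[str, int]


def run_cascade(calls: pd.DataFrame, ingroup: Iterable[str],
                outgroup: Iterable[str], annotations: pd.DataFrame,
                isoforms: pd.DataFrame, expression: pd.DataFrame,
                te_domains: Iterable[str] = frozenset(),
                tool_registry=None, min_peak: float = 50.0,
                rbbh: Mapping[str, Iterable[tuple[str, str]]] | None = None,
                tree_registry: Mapping[str, bool] | None = None,
                tree_ids: Mapping[str, str] | None = None,
                proteome_priority: Sequence[str] | None = None,
                ) -> CascadeResult:
    """Run the full filtering cascade in its canonical order:

    consensus → outgroup exclusion → unannotated → longest isoform →
    expression → RBBH/evidence report.

    Returns the trace, the final gene set and the evidence report.
    """
    trace = FilterTrace()
    universe = set(calls["gene"].unique())

    consensus = consensus_echinoderm(calls, ingroup, tool_registry)
    trace.add("consensus", universe, consensus)

    no_outgroup = exclude_outgroup_homologs(consensus, calls, outgroup)
    trace.add("outgroup_exclusion", consensus, no_outgroup)

    unannotated = unannotated_only(no_outgroup, annotations, te_domains)
    trace.add("unannotated", no_outgroup, unannotated)

    longest = longest_isoform(unannotated, isoforms)
    trace.add("longest_isoform", unannotated, longest)

    expressed = expression_filter(longest, expression, min_peak)
    trace.add("expression", longest, expressed)

    report, summary = evidence_report(
        expressed, rbbh or {}, annotations, tree_registry or {},
        tree_ids, proteome_priority)
    return CascadeResult(trace, expressed, report, summary)
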