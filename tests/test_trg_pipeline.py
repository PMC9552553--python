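import io
import random
import statistics

import pandas as pd
import pytest

from phylotrg.errors import DataError
from phylotrg.phylo_io import HitTable, read_hit_table
from phylotrg.trg_pipeline import (
    consensus_echinoderm,
    evidence_report,
    exclude_outgroup_homologs,
    expression_filter,
    filter_hits,
    longest_isoform,
    reciprocal_best_hits,
    run_cascade,
    unannotated_only,
)
from phylotrg.synthetic_data import simulate_expression, simulate_study


def _hit(q, s, evalue, bit=200.0, qstart=1, qend=100):
    return f"{q}\t{s}\t90.0\t100\t5\t0\t{qstart}\t{qend}\t1\t100\t{evalue}\t{bit}"


def _hits(rows, lengths):
    return read_hit_table(io.StringIO("\n".join(rows)), lengths)


# ---------------------------------------------------------------------------
# hit filtering
# ---------------------------------------------------------------------------

def test_significant_hit_retained():
    hits = _hits([_hit("q1", "s1", 1e-6, qstart=20, qend=79)], {"q1": 100})
    assert len(filter_hits(hits)) == 1  # e-value 1e-6, 60/100 coverage


@pytest.mark.parametrize("evalue,qstart,qend", [
    (1e-4, 20, 79),   # fails the e-value threshold
    (1e-6, 30, 69),   # 40% coverage fails the overlap threshold
    (1e-5, 20, 79),   # boundary e-value: strict less-than
])
def test_insignificant_hit_removed(evalue, qstart, qend):
    hits = _hits([_hit("q1", "s1", evalue, qstart=qstart, qend=qend)],
                 {"q1": 100})
    assert len(filter_hits(hits)) == 0


def test_per_query_cap_keeps_closest_hits():
    rows = [_hit("q1", f"s{i:03d}", float(f"1e-{200 - i}")) for i in range(200)]
    hits = _hits(rows, {"q1": 100})
    out = filter_hits(hits, max_hits=150)
    assert len(out) == 150
    # the kept hits are exactly the 150 smallest e-values
    expected = sorted(hits.df["evalue"])[:150]
    assert sorted(out.df["evalue"]) == expected


def test_unregistered_query_length_is_an_error():
    hits = _hits([_hit("q1", "s1", 1e-6)], {"other": 100})
    with pytest.raises(DataError, match="q1"):
        filter_hits(hits)


# ---------------------------------------------------------------------------
# consensus & outgroup exclusion
# ---------------------------------------------------------------------------

def _calls(rows):
    return pd.DataFrame(rows, columns=["gene", "tool", "target_species",
                                       "target_gene", "one_to_one"])


def test_consensus_requires_every_tool_for_every_species():
    tools = ["T1", "T2", "T3", "T4", "T5"]
    rows = [("gA", t, sp, f"{sp}.gA", True)
            for t in tools for sp in ("X", "Y")]
    # gB is missed by T5 for species Y
    rows += [("gB", t, sp, f"{sp}.gB", True)
             for t in tools for sp in ("X", "Y") if not (t == "T5" and sp == "Y")]
    out = consensus_echinoderm(_calls(rows), ingroup={"X", "Y"},
                               tool_registry=tools)
    assert out == {"gA"}


def test_consensus_empty_calls():
    assert consensus_echinoderm(_calls([]), ingroup={"X"},
                                tool_registry=["T1"]) == set()


def test_per_species_tool_registry():
    # tool T2 is not required for species Y (mirrors a tool lacking a
    # comparison for one lineage)
    rows = [("gA", "T1", "X", "x", True), ("gA", "T2", "X", "x", True),
            ("gA", "T1", "Y", "y", True)]
    registry = {"X": ["T1", "T2"], "Y": ["T1"]}
    out = consensus_echinoderm(_calls(rows), ingroup={"X", "Y"},
                               tool_registry=registry)
    assert out == {"gA"}


def test_any_outgroup_call_excludes():
    calls = _calls([("gA", "T1", "MOUSE", "m1", False)])
    assert exclude_outgroup_homologs({"gA", "gB"}, calls,
                                     {"MOUSE", "HUMAN"}) == {"gB"}


# ---------------------------------------------------------------------------
# annotation / isoform / expression
# ---------------------------------------------------------------------------

def _annotations(rows):
    return pd.DataFrame(rows, columns=["gene", "go_terms", "domains"])


def test_annotated_gene_removed():
    ann = _annotations([("gA", frozenset({"GO:0005515"}), frozenset()),
                        ("gB", frozenset(), frozenset())])
    assert unannotated_only({"gA", "gB", "gC"}, ann) == {"gB", "gC"}


def test_te_domain_gene_removed():
    ann = _annotations([("gA", frozenset(), frozenset({"PF03221"}))])
    assert unannotated_only({"gA"}, ann, te_domains={"PF03221"}) == set()


def test_longest_isoform_selection_and_tie_rule():
    iso = pd.DataFrame([("g1", "g1.a", 100), ("g1", "g1.b", 250),
                        ("g2", "g2.a", 200), ("g2", "g2.b", 200),
                        ("g3", "g3.a", 50)],
                       columns=["gene", "isoform", "length"])
    out = longest_isoform({"g1.a", "g1.b", "g2.a", "g2.b", "g3.a"}, iso)
    assert out == {"g1.b", "g2.a", "g3.a"}  # ties break by isoform ID


def test_expression_threshold_is_strict():
    expr = pd.DataFrame({"t0": [51.0, 50.0, 0.0], "t1": [10.0, 49.0, 0.0]},
                        index=["hi", "edge", "silent"])
    out = expression_filter({"hi", "edge", "silent"}, expr, min_peak=50.0)
    assert out == {"hi"}


def test_negative_tpm_rejected():
    expr = pd.DataFrame({"t0": [-1.0]}, index=["g1"])
    with pytest.raises(DataError):
        expression_filter({"g1"}, expr)


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def test_symmetric_best_hits_recovered():
    ab = _hits([_hit("a1", "b1", 1e-30), _hit("a1", "b2", 1e-10)], {"a1": 100})
    ba = _hits([_hit("b1", "a1", 1e-30), _hit("b2", "a1", 1e-8)], {"b1": 100, "b2": 100})
    assert reciprocal_best_hits(ab, ba) == [("a1", "b1")]


def test_non_reciprocal_best_yields_no_pair():
    ab = _hits([_hit("a1", "b1", 1e-30)], {"a1": 100})
    ba = _hits([_hit("b1", "c1", 1e-40), _hit("b1", "a1", 1e-30)],
               {"b1": 100})
    assert reciprocal_best_hits(ab, ba) == []


def test_ambiguous_tie_yields_no_pair():
    ab = _hits([_hit("a1", "b1", 1e-30, bit=200),
                _hit("a1", "b2", 1e-30, bit=200)], {"a1": 100})
    ba = _hits([_hit("b1", "a1", 1e-30)], {"b1": 100})
    assert reciprocal_best_hits(ab, ba) == []


def test_rbbh_symmetry_random_tables(rng):
    """RBBH pairs from (A,B) equal the transposed pairs from (B,A)."""
    for _ in range(20):
        n_a, n_b = rng.randint(2, 8), rng.randint(2, 8)
        rows_ab, rows_ba = [], []
        for i in range(n_a):
            for j in range(n_b):
                if rng.random() < 0.4:
                    e = 10.0 ** -rng.randint(8, 40)
                    bit = float(rng.randint(50, 400))
                    rows_ab.append(_hit(f"a{i}", f"b{j}", e, bit=bit))
                    rows_ba.append(_hit(f"b{j}", f"a{i}", e, bit=bit))
        la = {f"a{i}": 100 for i in range(n_a)}
        lb = {f"b{j}": 100 for j in range(n_b)}
        ab = _hits(rows_ab, la) if rows_ab else HitTable(
            read_hit_table(io.StringIO("")).df, la)
        ba = _hits(rows_ba, lb) if rows_ba else HitTable(
            read_hit_table(io.StringIO("")).df, lb)
        fwd = set(reciprocal_best_hits(ab, ba))
        rev = {(a, b) for b, a in reciprocal_best_hits(ba, ab)}
        assert fwd == rev


# ---------------------------------------------------------------------------
# evidence report & cascade
# ---------------------------------------------------------------------------

def test_empty_gene_set_report():
    report, summary = evidence_report([], {}, _annotations([]), {})
    assert len(report) == 0
    assert summary == {"total": 0, "with_rbbh": 0, "ontology_absent": 0,
                       "with_tree": 0, "without_tree": 0, "no_evidence": 0}


def test_rbbh_partner_follows_proteome_priority():
    rbbh = {"NEMVE": [("g1", "nv1")], "BRAFL": [("g1", "bf1")]}
    report, _ = evidence_report(["g1"], rbbh, _annotations([]), {},
                                proteome_priority=["BRAFL", "NEMVE"])
    assert report.loc[0, "rbbh"] == "bf1"
    assert "NEMVE:nv1" in report.loc[0, "rbbh_all"]
    assert "BRAFL:bf1" in report.loc[0, "rbbh_all"]


def test_cascade_reproduces_reference_trace():
    """With the default synthetic-study sizes the trace narrows
    145 -> 31 -> 14 through the annotation/isoform and expression stages."""
    study = simulate_study(seed=5)
    result = run_cascade(**study.cascade_kwargs())
    by_stage = {s: (i, o) for s, i, o in result.trace.counts()}
    assert by_stage["outgroup_exclusion"][1] == 145
    assert by_stage["longest_isoform"][1] == 31
    assert by_stage["expression"][1] == 14
    assert result.summary["total"] == 14
    assert result.summary["with_rbbh"] == 7
    assert result.summary["no_evidence"] == 1


def test_cascade_counts_are_monotone_and_chained():
    study = simulate_study(seed=2)
    result = run_cascade(**study.cascade_kwargs())
    counts = result.trace.counts()
    for (_, n_in, n_out) in counts:
        assert n_out <= n_in
    for (_, _, prev_out), (_, next_in, _) in zip(counts, counts[1:]):
        assert prev_out == next_in


def test_cascade_recovers_planted_set_exactly():
    for seed in (0, 1, 2):
        study = simulate_study(seed=seed)
        result = run_cascade(**study.cascade_kwargs())
        assert result.final_genes == set(study.planted_trgs)


def test_permissive_thresholds_degenerate_to_consensus_minus_annotated():
    study = simulate_study(seed=3)
    kwargs = study.cascade_kwargs()
    kwargs["min_peak"] = -1.0  # every expressed gene passes
    result = run_cascade(**kwargs)
    consensus = consensus_echinoderm(study.calls, study.ingroup,
                                     study.tool_registry)
    no_out = exclude_outgroup_homologs(consensus, study.calls,
                                       study.outgroup)
    unann = unannotated_only(no_out, study.annotations, study.te_domains)
    expected = longest_isoform(unann, study.isoforms)
    assert result.final_genes == expected


def test_unannotated_and_isoform_stages_commute(rng):
    for seed in range(5):
        study = simulate_study(seed=seed)
        genes = set(study.calls["gene"].unique())
        a = longest_isoform(
            unannotated_only(genes, study.annotations, study.te_domains),
            study.isoforms)
        b = unannotated_only(
            longest_isoform(genes, study.isoforms),
            study.annotations, study.te_domains)
        assert a == b


def test_planted_recovery_degrades_with_tool_error():
    """Precision and recall are 1.0 at zero tool error; mean recall
    declines as the per-tool false-negative rate grows."""
    rates = [0.0, 0.05, 0.10]
    mean_recall = {}
    for rate in rates:
        recalls = []
        for seed in range(30):
            study = simulate_study(seed=seed, fn_rate=rate)
            result = run_cascade(**study.cascade_kwargs())
            planted = set(study.planted_trgs)
            found = result.final_genes
            precision = (len(found & planted) / len(found)) if found else 1.0
            recalls.append(len(found & planted) / len(planted))
            assert precision == 1.0
        mean_recall[rate] = statistics.mean(recalls)
    assert mean_recall[0.0] == 1.0
    assert mean_recall[0.0] > mean_recall[0.05] > mean_recall[0.10]


def test_expression_simulation_feeds_filter():
    genes = [f"g{i}" for i in range(40)]
    expr = simulate_expression(genes, peak_fraction=0.0, seed=4)
    assert expression_filter(set(genes), expr) == set()
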