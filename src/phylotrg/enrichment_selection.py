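"""GO-term enrichment between gene lists and selection-site summaries.

Enrichment follows the FatiGO recipe: for each term a 2×2 table of
(study genes with the term, study genes without it, remaining background
genes with the term, rest) is tested with the hypergeometric distribution —
one-sided over-representation by default, two-sided optionally — and
p-values are adjusted across terms with Benjamini–Hochberg FDR.

Selection summaries count, per gene, the alignment sites whose posterior
probability of positive or negative selection meets a threshold (0.95 by
default, inclusive) and report the corresponding percentages.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = ["go_enrichment", "selection_summary"]


def go_enrichment(study: Iterable[str], background: Iterable[str],
                  annotations: Mapping[str, Iterable[str]],
                  alternative: str = "greater") -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``study`` against
    ``background``.

    ``annotations`` maps gene → term collection.  ``alternative`` is
    ``"greater"`` (over-representation, the default), ``"less"`` or
    ``"two-sided"`` (doubled smaller tail, capped at 1).  Terms annotating
    no study gene and no background-minus-study gene are skipped.  Returns
    one row per term with counts, raw p, BH-adjusted p and direction.
    """
    study = set(study)
    background = set(background)
    if not background:
        raise DataError("background gene set is empty")
    offenders = sorted(study - background)
    if offenders:
        raise DataError(
            f"study genes missing from background: {offenders[:10]}")
    term_to_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            term_to_genes.setdefault(term, set()).add(gene)
    N, n = len(background), len(study)
    rows = []
    for term in sorted(term_to_genes):
        genes_with = term_to_genes[term]
        K = len(genes_with)
        k = len(genes_with & study)
        if k == 0 and K == 0:
            continue
        if k == 0 and len(genes_with - study) == 0:
            continue  # term absent from both compartments
        upper = float(hypergeom.sf(k - 1, N, K, n))   # P(X >= k)
        lower = float(hypergeom.cdf(k, N, K, n))      # P(X <= k)
        if alternative == "greater":
            p = upper
        elif alternative == "less":
            p = lower
        elif alternative == "two-sided":
            p = min(1.0, 2 * min(upper, lower))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        expected = n * K / N
        rows.append({
            "term": term,
            "study_count": k,
            "study_size": n,
            "background_count": K,
            "background_size": N,
            "p_value": min(1.0, p),
            "direction": "over" if k >= expected else "under",
        })
    result = pd.DataFrame(rows, columns=["term", "study_count", "study_size",
                                         "background_count",
                                         "background_size", "p_value",
                                         "direction"])
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"],
                                             method="fdr_bh")[1]
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    return result


def selection_summary(site_table: pd.DataFrame, threshold: float = 0.95
                      ) -> pd.DataFrame:
    """Summarize per-site selection posteriors per gene.

    ``site_table`` has columns gene, site, pp_positive, pp_negative with
    posteriors in [0, 1].  A site counts as positively (negatively) selected
    when its posterior meets ``threshold`` (inclusive).  Percentages are
    rounded to one decimal and undefined (NaN) for genes without sites.
    """
    for col in ("pp_positive", "pp_negative"):
        if col not in site_table.columns:
            raise DataError(f"site table is missing column {col!r}")
        vals = site_table[col]
        if len(vals) and ((vals < 0) | (vals > 1)).any():
            raise DataError(f"posterior outside [0, 1] in {col}")
    rows = []
    for gene, grp in site_table.groupby("gene", sort=True):
        total = len(grp)
        n_pos = int((grp["pp_positive"] >= threshold).sum())
        n_neg = int((grp["pp_negative"] >= threshold).sum())
        rows.append({
            "gene": gene,
            "sites_total": total,
            "sites_negative": n_neg,
            "sites_positive": n_pos,
            "pct_negative": round(100 * n_neg / total, 1) if total else
                            float("nan"),
            "pct_positive": round(100 * n_pos / total, 1) if total else
                            float("nan"),
        })
    return pd.DataFrame(rows, columns=["gene", "sites_total",
                                       "sites_negative", "sites_positive",
                                       "pct_negative", "pct_positive"])
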