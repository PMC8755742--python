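"""Hypergeometric over-representation of gene-set terms.

Query genes (those coding differentially abundant proteins) are tested
against each flat gene set from a GMT collection, with the panel's full
gene complement as the background universe.  Terms with fewer than three
query hits are excluded before Benjamini-Hochberg adjustment, and q < 0.05
declares enrichment — mirroring the standard over-representation recipe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalyteAnnotation, ValidationError
from .diffabund import bh_adjust

logger = logging.getLogger(__name__)


def map_analytes_to_genes(
    annotation: AnalyteAnnotation, analyte_ids
) -> tuple[set[str], int]:
    """Union of gene symbols for the given analytes.

    Multi-gene analytes contribute every listed symbol; duplicates
    collapse.  Analytes missing from the annotation are skipped with a
    warning; the number skipped is returned alongside the gene set.
    """
    genes: set[str] = set()
    skipped = 0
    known = set(annotation.table.index)
    for aid in analyte_ids:
        if aid not in known:
            skipped += 1
            continue
        genes.update(annotation.table.at[aid, "gene_symbols"])
    if skipped:
        logger.warning("%d analytes missing from the annotation were skipped", skipped)
    return genes, skipped


def hypergeometric_enrichment(
    query_genes,
    universe_genes,
    gene_sets: dict[str, dict],
    min_term_hits: int = 3,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each gene set against the universe.

    For a universe of N genes containing K term genes and a query of n
    genes with k term hits, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
    Terms with k < ``min_term_hits`` are excluded before BH adjustment;
    results are sorted by p.  ``enriched`` flags q < ``q_threshold``.
    """
    universe = {str(g).upper() for g in universe_genes}
    if not universe:
        raise ValidationError("empty gene universe")
    query = {str(g).upper() for g in query_genes}
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for term_id, rec in gene_sets.items():
        term_genes = {str(g).upper() for g in rec["genes"]} & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        if k < min_term_hits:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": rec.get("term_name", ""),
                "universe_size": N,
                "term_size": K,
                "query_size": n,
                "hits": k,
                "expected": n * K / N,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "universe_size",
            "term_size",
            "query_size",
            "hits",
            "expected",
            "p",
        ],
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["enriched"] = result["q"] < q_threshold
        result = result.sort_values(["p", "term_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        result["q"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
    return result
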