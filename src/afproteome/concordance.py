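"""Cross-omics fold-change concordance against an external study.

Matches this pipeline's per-analyte log2 fold changes to a prior study's
differential table by upper-cased gene symbol, restricts to molecules
significant in both studies, and reports the Spearman correlation and the
fraction changing in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalyteAnnotation, ValidationError


@dataclass
class ConcordanceResult:
    """Spearman rho, p, and the same-direction tally on the matched pairs."""

    n_common: int
    rho: float
    p: float
    same_direction: int
    same_direction_fraction: float
    pairs: pd.DataFrame


def harmonize_ids(
    de_table: pd.DataFrame,
    annotation: AnalyteAnnotation,
    prior: pd.DataFrame,
) -> pd.DataFrame:
    """Match analytes to prior-study rows on upper-cased gene symbols.

    Multi-gene analytes match when any of their symbols matches; an
    analyte matching several prior rows keeps every pair with a
    multiplicity flag.  Raises with a diagnostic when the symbol sets are
    disjoint.
    """
    if de_table.empty or prior.empty:
        raise ValidationError("both tables must be nonempty")
    prior_genes = {str(g).upper(): g for g in prior.index}
    rows = []
    for aid in de_table.index:
        if aid not in annotation.table.index:
            continue
        symbols = annotation.table.at[aid, "gene_symbols"]
        matches = [g for g in symbols if g in prior_genes]
        for g in matches:
            rows.append(
                {
                    "analyte_id": aid,
                    "gene": g,
                    "log2_fc_de": float(de_table.at[aid, "log2_fc"]),
                    "significant_de": bool(de_table.at[aid, "significant"]),
                    "log2_fc_prior": float(prior.at[prior_genes[g], "log2_fc"]),
                    "significant_prior": bool(prior.at[prior_genes[g], "significant"]),
                    "multiplicity": len(matches),
                }
            )
    if not rows:
        de_genes = sorted(annotation.genes_for(
            [a for a in de_table.index if a in annotation.table.index]
        ))[:5]
        raise ValidationError(
            "no overlap between analyte gene symbols and prior study ids "
            f"(panel symbols look like {de_genes}, prior ids like "
            f"{sorted(prior_genes)[:5]})"
        )
    return pd.DataFrame(rows)


def concordance(
    pairs: pd.DataFrame, require_both_significant: bool = True
) -> ConcordanceResult:
    """Spearman correlation and same-direction fraction of matched pairs.

    With ``require_both_significant`` only pairs significant in both
    studies are kept.  A zero fold change on either side counts as a
    direction disagreement.  At least 3 pairs are required after
    filtering.
    """
    kept = pairs
    if require_both_significant:
        kept = pairs[pairs["significant_de"] & pairs["significant_prior"]]
    if len(kept) < 3:
        raise ValidationError(
            f"only {len(kept)} matched pairs after the significance filter; "
            "need >= 3"
        )
    a = kept["log2_fc_de"].to_numpy(float)
    b = kept["log2_fc_prior"].to_numpy(float)
    rho, p = stats.spearmanr(a, b)
    same = int(np.sum((np.sign(a) == np.sign(b)) & (a != 0) & (b != 0)))
    return ConcordanceResult(
        n_common=len(kept),
        rho=float(rho),
        p=float(p),
        same_direction=same,
        same_direction_fraction=same / len(kept),
        pairs=kept.reset_index(drop=True),
    )
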