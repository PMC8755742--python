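"""Tissue-specific signature scoring of the proteome.

A gene is specific to a tissue when its atlas expression there is at least
30x the median over the other tissues.  Per tissue, up to the top 20 such
genes measured on the panel form the signature.  Each signature analyte's
log2 abundance is Z-scored against the midtrimester reference group
(subtract the reference mean, divide by the reference SD), the Z-scores
are averaged per sample into a tissue score, and scores are compared
between groups with the Wilcoxon rank-sum test followed by BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GROUP_MIDTRIMESTER,
    GROUP_TERM,
    LOG2,
    AbundanceMatrix,
    AnalyteAnnotation,
    ValidationError,
)
from .diffabund import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class TissueSignature:
    """One tissue's signature genes with their specificity ratios."""

    tissue: str
    genes: list[str]
    ratios: list[float]


def build_tissue_signatures(
    atlas: pd.DataFrame,
    panel_genes,
    specificity_ratio: float = 30.0,
    top_n: int = 20,
    comparator: str = "median",
) -> list[TissueSignature]:
    """Derive tissue-specific signatures from a gene x tissue atlas.

    A gene is specific to tissue *t* when its expression there is at least
    ``specificity_ratio`` times the ``comparator`` (median by default, max
    optionally) of its expression over the other tissues.  Specific genes
    are intersected with the panel and capped at the ``top_n`` highest
    ratios (ties broken by gene id).  Tissues with no panel-measured
    specific genes are excluded with a warning.
    """
    if atlas.shape[1] < 2:
        raise ValidationError("need at least 2 tissues to define specificity")
    if comparator not in ("median", "max"):
        raise ValidationError("comparator must be 'median' or 'max'")
    panel = {str(g).upper() for g in panel_genes}
    values = atlas.to_numpy(float)
    genes = atlas.index.to_numpy()
    signatures = []
    for j, tissue in enumerate(atlas.columns):
        others = np.delete(values, j, axis=1)
        baseline = (
            np.median(others, axis=1) if comparator == "median" else others.max(axis=1)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(baseline > 0, values[:, j] / baseline, np.inf)
            ratio = np.where(values[:, j] == 0, 0.0, ratio)
        specific = ratio >= specificity_ratio
        rows = pd.DataFrame(
            {"gene": genes[specific], "ratio": ratio[specific]}
        )
        rows = rows[rows["gene"].isin(panel)]
        rows = rows.sort_values(
            ["ratio", "gene"], ascending=[False, True], kind="stable"
        ).head(top_n)
        if rows.empty:
            logger.warning("tissue %r has no panel-measured specific genes", tissue)
            continue
        signatures.append(
            TissueSignature(
                tissue=str(tissue),
                genes=rows["gene"].tolist(),
                ratios=rows["ratio"].tolist(),
            )
        )
    return signatures


def _signature_analytes(
    signature: TissueSignature, annotation: AnalyteAnnotation
) -> list[str]:
    """Panel analytes realizing a signature; any mapped symbol qualifies."""
    wanted = set(signature.genes)
    hits = []
    for aid, symbols in annotation.table["gene_symbols"].items():
        if wanted & set(symbols):
            hits.append(aid)
    return hits


def score_tissue_signatures(
    matrix: AbundanceMatrix,
    signatures: list[TissueSignature],
    annotation: AnalyteAnnotation,
    metadata,
    reference_group: str = GROUP_MIDTRIMESTER,
) -> pd.DataFrame:
    """Sample x tissue mean Z-scores against the reference group.

    Each signature analyte is standardized by the reference group's mean
    and SD; a sample's tissue score is the mean Z over the signature's
    analytes.  Analytes with zero reference SD are dropped with a warning.
    """
    if matrix.scale != LOG2:
        raise ValidationError("tissue scoring expects a log2 matrix")
    table = metadata.table if hasattr(metadata, "table") else metadata
    ref_samples = table.index[table["group"] == reference_group]
    if len(ref_samples) < 2:
        raise ValidationError("reference group needs >= 2 samples")
    scores = {}
    for sig in signatures:
        analytes = [
            a for a in _signature_analytes(sig, annotation) if a in matrix.data.columns
        ]
        if not analytes:
            raise ValidationError(
                f"signature {sig.tissue!r} has no analytes in the matrix"
            )
        block = matrix.data[analytes]
        mu = block.loc[ref_samples].mean(axis=0)
        sd = block.loc[ref_samples].std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "tissue %r: dropped %d zero-reference-SD analytes",
                sig.tissue,
                int((~keep).sum()),
            )
        if not keep.any():
            raise ValidationError(
                f"signature {sig.tissue!r} has no analytes with positive "
                "reference SD"
            )
        z = (block.loc[:, keep] - mu[keep]) / sd[keep]
        scores[sig.tissue] = z.mean(axis=1)
    out = pd.DataFrame(scores, index=matrix.data.index)
    out.columns.name = "tissue"
    return out


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    The exact null distribution is used when both groups have <= 25
    observations and there are no ties; otherwise the normal approximation
    with tie correction is used.  W is the Mann-Whitney U of the first
    group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both groups need >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValidationError("scores are constant across both groups")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_tissue_scores(
    scores: pd.DataFrame,
    metadata,
    q_threshold: float = 0.05,
    groups: tuple[str, str] = (GROUP_TERM, GROUP_MIDTRIMESTER),
) -> pd.DataFrame:
    """Per-tissue group comparison of the mean Z-scores.

    Returns W, p, BH-adjusted q, the group medians, the direction of the
    term-versus-midtrimester difference, and the significance flag.
    """
    table = metadata.table if hasattr(metadata, "table") else metadata
    a_ids = table.index[table["group"] == groups[0]]
    b_ids = table.index[table["group"] == groups[1]]
    rows = []
    for tissue in scores.columns:
        a = scores.loc[scores.index.intersection(a_ids), tissue].to_numpy(float)
        b = scores.loc[scores.index.intersection(b_ids), tissue].to_numpy(float)
        w, p = wilcoxon_rank_sum(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "tissue": tissue,
                f"median_{groups[0]}": med_a,
                f"median_{groups[1]}": med_b,
                "W": w,
                "p": p,
                "direction": "increased" if med_a >= med_b else "decreased",
            }
        )
    result = pd.DataFrame(rows).set_index("tissue")
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] < q_threshold
    return result
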