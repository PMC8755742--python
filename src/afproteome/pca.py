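"""Principal-component summary of the proteome and PC-trait correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LOG2, AbundanceMatrix, ValidationError


@dataclass
class PCAResult:
    """Scores (samples x components), orthonormal loadings, variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    dropped_analytes: list
    centered: bool
    unit_scaled: bool


def compute_pca(
    matrix: AbundanceMatrix,
    center: bool = True,
    unit_scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """SVD principal components of the (column-standardized) log2 matrix.

    Zero-variance analytes are dropped (and recorded) when unit scaling is
    requested.  Component signs follow a deterministic convention: the
    largest-magnitude loading of each component is positive.
    """
    if matrix.scale != LOG2:
        raise ValidationError("PCA expects a log2-scale matrix")
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = matrix.values.copy()
    cols = list(matrix.data.columns)
    dropped: list = []
    sd = X.std(axis=0, ddof=1)
    if unit_scale:
        keep = sd > 0
        dropped = [c for c, k in zip(cols, keep) if not k]
        X = X[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]
        sd = sd[keep]
    if center:
        X = X - X.mean(axis=0)
    if unit_scale:
        X = X / sd
    max_rank = min(X.shape[0] - 1 if center else X.shape[0], X.shape[1])
    if n_components is None:
        n_components = max_rank
    if n_components > min(X.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(dims)={min(X.shape)}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total_var = (X**2).sum() / (X.shape[0] - 1 if center else X.shape[0])
    explained = s**2 / (X.shape[0] - 1 if center else X.shape[0])
    frac = explained / total_var if total_var > 0 else np.zeros_like(explained)
    comp = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=matrix.data.index, columns=comp
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=cols, columns=comp)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=frac[:n_components],
        dropped_analytes=dropped,
        centered=center,
        unit_scaled=unit_scale,
    )


def pc_trait_correlation(scores, trait) -> tuple[float, float]:
    """Pearson correlation of one component's scores with a sample trait.

    Because a principal component's sign is arbitrary (fixed here only by
    a loadings convention), |r| is the scale-free quantity; the signed r is
    returned and callers may take its absolute value.
    """
    scores = np.asarray(scores, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if scores.shape != trait.shape:
        raise ValidationError("scores and trait must have equal length")
    if np.ptp(trait) == 0:
        raise ValidationError("trait is constant")
    r, p = stats.pearsonr(scores, trait)
    return float(r), float(p)
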