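"""Signed weighted correlation network analysis of modulated proteins.

Follows the weighted correlation network recipe on the gestational-age
modulated analytes: biweight midcorrelation (bicor) between analyte
profiles, signed soft-threshold adjacency ``((1 + rho)/2)**beta`` with
beta = 22, topological overlap similarity, average-linkage clustering of
the overlap dissimilarity with a static cut, a size filter that sends
small clusters to a background/noise module (label 0), and iterative
merging of modules with highly correlated eigenprofiles.  Modules are
summarized by eigenprofiles (first principal component of the member
profiles), per-analyte kME hub scores, and LOESS gestational-age curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

#: Tuning constant of the biweight midcorrelation: deviations beyond
#: 9 * MAD get zero weight.
BICOR_C = 9.0


def _bicor_transform(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column robust standardization used by bicor.

    Returns the weighted deviations (already normalised to unit length)
    and a mask of columns with zero median absolute deviation, which fall
    back to Pearson standardization.
    """
    med = np.median(X, axis=0)
    dev = X - med
    mad = np.median(np.abs(dev), axis=0)
    zero_mad = mad == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (BICOR_C * mad)
    u[:, zero_mad] = 0.0
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    xw = dev * w
    if zero_mad.any():
        # Pearson fallback for MAD-degenerate columns
        xm = X[:, zero_mad] - X[:, zero_mad].mean(axis=0)
        xw[:, zero_mad] = xm
    norm = np.sqrt((xw**2).sum(axis=0))
    norm[norm == 0] = 1.0
    return xw / norm, zero_mad


def bicor_matrix(X) -> np.ndarray:
    """Biweight midcorrelation matrix between columns of ``X``.

    ``X`` is samples x analytes with at least 4 samples.  Columns whose
    median absolute deviation is zero are correlated by Pearson instead,
    with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValidationError("bicor needs a 2-D matrix with >= 4 samples")
    xw, zero_mad = _bicor_transform(X)
    if zero_mad.any():
        logger.warning(
            "bicor: %d columns with zero MAD fell back to Pearson",
            int(zero_mad.sum()),
        )
    rho = xw.T @ xw
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors."""
    return float(bicor_matrix(np.column_stack([x, y]))[0, 1])


def signed_adjacency(corr: np.ndarray, beta: float = 22.0) -> np.ndarray:
    """Signed soft-threshold adjacency ``((1 + rho)/2)**beta``."""
    if beta < 1:
        raise ValidationError("soft-threshold power beta must be >= 1")
    corr = np.asarray(corr, dtype=float)
    if corr.min() < -1.0 - 1e-9 or corr.max() > 1.0 + 1e-9:
        raise ValidationError("correlations must lie in [-1, 1]")
    adj = ((1.0 + np.clip(corr, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a symmetric adjacency in [0, 1].

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``k`` the connectivity (row sum excluding the diagonal).
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValidationError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1.0 + 1e-9:
        raise ValidationError("adjacency values must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


@dataclass
class ModuleAssignment:
    """Module labels (1..K by decreasing size; 0 = background/noise)."""

    labels: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> list:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


@dataclass
class EigenprofileSet:
    """Per-module eigenprofiles (samples x modules) and variance explained."""

    profiles: pd.DataFrame
    variance_explained: dict[int, float]


def _eigenprofile(block: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of standardized member profiles, plus variance explained."""
    Z = block - block.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = Z / sd
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    profile = U[:, 0]
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.size else 1.0
    # orient so that the mean member correlation is nonnegative
    corr = (Z / np.sqrt((Z**2).sum(axis=0))).T @ (profile / np.linalg.norm(profile))
    if corr.mean() < 0:
        profile = -profile
    return profile, var_explained


def module_eigenprofiles(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[EigenprofileSet, pd.DataFrame]:
    """Eigenprofiles and kME for each module.

    ``expr`` is samples x analytes (log2).  The eigenprofile is the
    unit-norm first principal component of the module's standardized
    member profiles, oriented so the mean member correlation is >= 0.
    kME(analyte, module) is the Pearson correlation of the analyte's
    profile with the eigenprofile, computed for every analyte.
    """
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValidationError("no modules to summarize")
    profiles = {}
    var_explained = {}
    for m in modules:
        members = labels.index[labels == m]
        block = expr[members].to_numpy(float)
        if block.shape[1] == 1:
            logger.warning("module %d has a single member", m)
            v = block[:, 0] - block[:, 0].mean()
            profiles[m] = v / np.linalg.norm(v)
            var_explained[m] = 1.0
            continue
        profiles[m], var_explained[m] = _eigenprofile(block)
    prof = pd.DataFrame(profiles, index=expr.index)
    prof.columns.name = "module"
    X = expr.to_numpy(float)
    Xc = X - X.mean(axis=0)
    xnorm = np.sqrt((Xc**2).sum(axis=0))
    xnorm[xnorm == 0] = 1.0
    kme = {}
    for m in modules:
        e = prof[m].to_numpy()
        ec = e - e.mean()
        kme[m] = (Xc / xnorm).T @ (ec / np.linalg.norm(ec))
    kme_table = pd.DataFrame(kme, index=expr.columns)
    kme_table.columns.name = "module"
    return EigenprofileSet(profiles=prof, variance_explained=var_explained), kme_table


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber modules 1..K by decreasing size, keeping 0 as background."""
    out = np.zeros_like(labels)
    sizes = [(int((labels == m).sum()), m) for m in set(labels) if m != 0]
    for new, (_, old) in enumerate(
        sorted(sizes, key=lambda t: (-t[0], t[1])), start=1
    ):
        out[labels == old] = new
    return out


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    min_module_size: int = 20,
    cut_height: float | str = 0.995,
    merge_corr: float = 0.85,
) -> ModuleAssignment:
    """Cluster the topological-overlap dissimilarity into modules.

    Average-linkage hierarchical clustering of ``1 - TOM`` is cut at
    ``cut_height`` (or, with ``cut_height='auto'``, at the 99th percentile
    of the merge-height distribution).  Clusters smaller than
    ``min_module_size`` are relabeled to the background module 0, and
    modules whose eigenprofiles correlate above ``merge_corr`` are merged
    iteratively.  Final labels are ordered by decreasing module size.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if expr.shape[1] != n:
        raise ValidationError("expression matrix does not match the TOM dimension")
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method="average")
    if cut_height == "auto":
        cut_height = float(np.quantile(Z[:, 2], 0.99))
    clusters = fcluster(Z, t=float(cut_height), criterion="distance")
    labels = clusters.astype(int)
    for c in set(labels):
        if (labels == c).sum() < min_module_size:
            labels[labels == c] = 0
    labels = _relabel_by_size(labels)
    if not (labels > 0).any():
        logger.warning("no modules found at the given parameters")
        return ModuleAssignment(
            labels=pd.Series(labels, index=expr.columns, name="module")
        )
    # iterative eigenprofile merging
    while True:
        series = pd.Series(labels, index=expr.columns)
        modules = sorted(set(labels) - {0})
        if len(modules) < 2:
            break
        eigs, _ = module_eigenprofiles(expr, series)
        corr = eigs.profiles.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= merge_corr:
            break
        a, b = modules[i], modules[j]
        labels[labels == b] = a
        labels = _relabel_by_size(labels)
    labels = _relabel_by_size(labels)
    return ModuleAssignment(labels=pd.Series(labels, index=expr.columns, name="module"))


def select_hubs(
    kme: pd.DataFrame, assignment: ModuleAssignment, n: int = 4
) -> dict[int, list]:
    """Top-n members per module by kME; ties broken by analyte id."""
    hubs = {}
    for m in assignment.module_ids:
        members = assignment.members(m)
        if len(members) < n:
            logger.warning("module %d has fewer than %d members", m, n)
        ranked = (
            kme.loc[members, m]
            .sort_index()
            .sort_values(ascending=False, kind="stable")
        )
        hubs[m] = list(ranked.index[:n])
    return hubs


def loess_profile(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Local polynomial (default quadratic) regression with tricube weights.

    For each grid point the ``ceil(span * n)`` nearest observations get
    tricube weights on their scaled distances, and a weighted degree-2
    polynomial is fit; the fitted value at the grid point is returned.
    The default grid is evenly spaced across the data range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValidationError("LOESS needs >= 5 (x, y) points")
    if not 0 < span <= 1:
        raise ValidationError("span must lie in (0, 1]")
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 2)
    if q > n:
        raise ValidationError("span too small for the local sample size")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    fitted = np.empty_like(grid)
    for i, g in enumerate(grid):
        dist = np.abs(x - g)
        idx = np.argsort(dist, kind="stable")[:q]
        h = dist[idx].max()
        if h == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1.0 - (dist[idx] / h) ** 3) ** 3
        w[w < 0] = 0.0
        dx = x[idx] - g
        B = np.vander(dx, degree + 1, increasing=True)
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(B * W[:, None], y[idx] * W, rcond=None)
        fitted[i] = coef[0]
    return grid, fitted
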