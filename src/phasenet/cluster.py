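"""Sample PCA, correlation-distance Ward clustering, resistant correlations.

Clustering uses 1 - r (Pearson) as the dissimilarity with Ward's ward.D2
linkage (scipy's ``linkage(method="ward")`` on a condensed distance matrix
applies exactly the ward.D2 Lance-Williams recurrence).  PCA centers genes
but does not rescale them, matching the usual default for log-ratio data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PCAResult",
    "pca_samples",
    "correlation_distance",
    "correlation_distance_matrix",
    "ward_cluster",
    "signature_heatmap_order",
    "resistant_phase_correlations",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fractions: np.ndarray


def pca_samples(matrix: pd.DataFrame) -> PCAResult:
    """SVD-based PCA of samples, genes centered (no variance scaling).

    Component signs are fixed so that each component's largest-magnitude gene
    loading is positive, making the result deterministic.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant matrix: PCA undefined")
    # samples are the observations: rows of centered.T
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    # gene-wise centering zeroes the all-ones sample direction
    k = max(1, min(matrix.shape[0], matrix.shape[1] - 1))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    loadings = vt.T  # genes x components
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = u * s * flip
    var = s**2 / (matrix.shape[1] - 1)
    frac = var / (centered.var(axis=1, ddof=1).sum())
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comps),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comps),
        variance_fractions=frac,
    )


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation; in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def correlation_distance_matrix(matrix: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """Pairwise 1 - r distances between samples (columns) or genes (rows)."""
    data = matrix.to_numpy(dtype=float)
    if axis == "samples":
        labels = matrix.columns
        corr = np.corrcoef(data.T)
    elif axis == "genes":
        labels = matrix.index
        corr = np.corrcoef(data)
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if np.isnan(corr).any():
        raise ValueError("constant profiles: correlation distance undefined")
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


def ward_cluster(dist: pd.DataFrame) -> dict:
    """Ward (ward.D2) hierarchical clustering of a dissimilarity matrix.

    Returns the scipy linkage matrix, the leaf order and leaf labels.
    """
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    order = hierarchy.leaves_list(linkage)
    return {
        "linkage": linkage,
        "leaf_order": order,
        "labels": [dist.index[i] for i in order],
    }


def signature_heatmap_order(
    matrix: pd.DataFrame, meta: pd.DataFrame, n_clusters: int = 2
) -> dict:
    """Cluster both heatmap axes and cross-tabulate sample clusters vs phase.

    Both the sample and the gene axis use 1 - r distance with ward.D2.  The
    returned cross-table cuts the sample dendrogram at ``n_clusters`` and
    counts phase labels per cluster, the quantitative surface behind "does the
    expression signature separate the phases".
    """
    sample_tree = ward_cluster(correlation_distance_matrix(matrix, axis="samples"))
    gene_tree = ward_cluster(correlation_distance_matrix(matrix, axis="genes"))
    assign = hierarchy.fcluster(sample_tree["linkage"], t=n_clusters, criterion="maxclust")
    phase = meta.set_index("sample_id").loc[matrix.columns, "phase"]
    cross = pd.crosstab(pd.Series(assign, index=matrix.columns, name="cluster"), phase)
    return {
        "sample_tree": sample_tree,
        "gene_tree": gene_tree,
        "sample_clusters": pd.Series(assign, index=matrix.columns),
        "cross_table": cross,
    }


def resistant_phase_correlations(
    matrix: pd.DataFrame, meta: pd.DataFrame
) -> dict:
    """Pairwise Pearson r between resistant samples and each phase sample.

    Returns the full resistant x phase-sample correlation matrix and the mean
    correlation of each resistant sample to each phase group.
    """
    meta_idx = meta.set_index("sample_id")
    res_ids = [c for c in matrix.columns if meta_idx.loc[c, "phase"] == "resistant"]
    phase_ids = [c for c in matrix.columns if meta_idx.loc[c, "phase"] != "resistant"]
    if not res_ids:
        raise ValueError("no resistant samples in metadata")
    corr = np.corrcoef(matrix.to_numpy(dtype=float).T)
    full = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    pairwise = full.loc[res_ids, phase_ids]
    phases = meta_idx.loc[phase_ids, "phase"]
    means = pairwise.T.groupby(phases).mean().T
    return {"pairwise": pairwise, "mean_by_phase": means}
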