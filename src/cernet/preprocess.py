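"""Quantile normalization and sample-level QC.

Microarray intensities are quantile-normalized on the linear scale; all
downstream correlation, clustering and PCA operate on log2(x + 1) values.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import UserError, ValidationError
from .io import ExpressionMatrix


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) intensity distribution.

    After the call each sample's sorted value vector equals the across-sample
    mean of sorted vectors. Ties within a sample receive the mean of the
    reference values at their rank positions (limma's ``ties=TRUE``
    convention), so the operation is idempotent.
    """
    if m.scale != "linear":
        raise UserError("quantile normalization expects linear intensities")
    if m.n_samples < 2:
        raise UserError("quantile normalization needs at least 2 samples")
    x = m.values.to_numpy(dtype=float)
    n, k = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # average reference values over tied input values
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                mapped[order[s:e]] = reference[s:e].mean()
        out[:, j] = mapped
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values)


def _check_sample_variance(values: pd.DataFrame) -> None:
    sd = values.std(axis=0, ddof=0)
    flat = sd.index[sd == 0]
    if len(flat):
        raise ValidationError(f"zero-variance sample: {flat[0]!r}")


def sample_correlation_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples (QC heatmap input).

    Correlations are computed on the values as given; pass a log2 matrix for
    the conventional QC view.
    """
    if m.n_features < 3:
        raise UserError("need at least 3 features for sample correlations")
    values = m.values
    _check_sample_variance(values)
    r = np.corrcoef(values.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.columns, columns=values.columns)


def hierarchical_cluster_samples(m: ExpressionMatrix, linkage: str = "average"):
    """Agglomerative clustering of samples on correlation distance (1 - PCC).

    Returns the scipy linkage matrix; see :func:`dendrogram_newick` for a
    portable text export.
    """
    if linkage not in ("average", "complete"):
        raise UserError(f"unsupported linkage {linkage!r}")
    if m.n_samples < 2:
        raise UserError("need at least 2 samples to cluster")
    corr = sample_correlation_matrix(m).to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(0.0, (dist + dist.T) / 2.0)  # numerical symmetry
    return sch.linkage(squareform(dist, checks=False), method=linkage)


def dendrogram_newick(link: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def cut_two_clusters(link: np.ndarray, labels) -> list:
    """Sample labels of the two top-level clades, as a list of two sets."""
    assignment = sch.fcluster(link, t=2, criterion="maxclust")
    return [
        {lab for lab, a in zip(labels, assignment) if a == c}
        for c in sorted(set(assignment))
    ]


def pca_scores(m: ExpressionMatrix, k: int = 2):
    """Sample scores on the first k principal components.

    PCA is computed by SVD on feature-centered (not scaled) values as given
    (pass a log2 matrix for the conventional QC view); the sign of each
    component is fixed by forcing its largest-magnitude feature loading
    positive.

    Returns
    -------
    scores : pandas.DataFrame, samples x k
    variance_fractions : numpy.ndarray, length k, non-increasing
    """
    max_k = min(m.n_samples - 1, m.n_features)
    if not 1 <= k <= max_k:
        raise UserError(f"k={k} out of range 1..{max_k}")
    values = m.values.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| feature positive per component
    for i in range(k):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i] = -vt[i]
    scores = (vt * s[:, None]).T  # samples x k
    total_var = (centered ** 2).sum()
    fractions = (s ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=m.values.columns, columns=cols), fractions
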