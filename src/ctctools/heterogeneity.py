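"""Unsupervised structure analysis of Z-scored single-cell matrices.

Cells are the observations (each cell is a vector of per-gene Z-scores):
agglomerative hierarchical clustering (default Euclidean distance, complete
linkage), t-SNE embedding into 2 or 3 dimensions, and pairwise Spearman rank
correlation between cells with Bonferroni-adjusted two-sided p-values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.manifold import TSNE

from .matrix import ExpressionMatrix


@dataclasses.dataclass
class ClusteringResult:
    """Agglomerative tree over cells (scipy linkage encoding)."""

    linkage: np.ndarray          # (n-1, 4) merge table: ids, height, size
    cell_ids: list[str]
    leaf_order: list[str]
    labels: pd.Series | None     # flat labels when cut at k groups
    metric: str
    method: str


@dataclasses.dataclass
class EmbeddingResult:
    cell_ids: list[str]
    coordinates: np.ndarray      # cells x dims
    perplexity: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = list("xyz"[: self.coordinates.shape[1]])
        return pd.DataFrame(self.coordinates, index=self.cell_ids, columns=cols)


@dataclasses.dataclass
class CorrelationMatrix:
    ids: list[str]
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_pairs: int
    undefined: list[str]         # ids with constant vectors (rho undefined)


class HierarchicalClusterer(ClusterMixin, BaseEstimator):
    """sklearn-style wrapper: fit(X) on cells x features, X -> linkage_/labels_.

    Deterministic given the input; ties in the merge order follow scipy's
    lowest-index convention.
    """

    def __init__(self, n_clusters: int | None = None, metric: str = "euclidean",
                 method: str = "complete") -> None:
        self.n_clusters = n_clusters
        self.metric = metric
        self.method = method

    def fit(self, X, y=None):
        X = pd.DataFrame(X).astype(float)
        if X.shape[0] < 2:
            raise ValueError("clustering needs at least 2 cells")
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError("non-finite values in clustering input")
        self.linkage_ = hierarchy.linkage(
            pdist(X.to_numpy(), metric=self.metric), method=self.method
        )
        self.leaf_order_ = list(X.index[hierarchy.leaves_list(self.linkage_)])
        if self.n_clusters is not None:
            flat = hierarchy.fcluster(self.linkage_, self.n_clusters,
                                      criterion="maxclust")
            self.labels_ = flat - 1
        else:
            self.labels_ = None
        self.cell_ids_ = list(X.index)
        return self


def hierarchical_cluster(
    z: ExpressionMatrix,
    metric: str = "euclidean",
    method: str = "complete",
    n_clusters: int | None = None,
) -> ClusteringResult:
    """Cluster cells of a stage=zscore matrix (genes x cells)."""
    z.require_stage("zscore", "hierarchical_cluster")
    est = HierarchicalClusterer(n_clusters=n_clusters, metric=metric,
                                method=method).fit(z.values.T)
    labels = None
    if est.labels_ is not None:
        labels = pd.Series(est.labels_, index=est.cell_ids_, name="cluster")
    return ClusteringResult(
        linkage=est.linkage_, cell_ids=est.cell_ids_,
        leaf_order=est.leaf_order_, labels=labels,
        metric=metric, method=method,
    )


def tsne_embed(
    z: ExpressionMatrix,
    dims: int = 2,
    perplexity: float = 10.0,
    seed: int = 0,
) -> EmbeddingResult:
    """t-SNE embedding of cells; reproducible under a fixed seed.

    Requires perplexity < (n_cells - 1) / 3, the usual validity bound for
    the conditional-neighborhood construction.
    """
    z.require_stage("zscore", "tsne_embed")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    n = len(z.cell_ids)
    if not perplexity < (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} cells "
            f"(needs perplexity < (n-1)/3 = {(n - 1) / 3:.2f})"
        )
    tsne = TSNE(n_components=dims, perplexity=perplexity, random_state=seed,
                init="pca")
    coords = tsne.fit_transform(z.values.T.to_numpy())
    return EmbeddingResult(cell_ids=list(z.cell_ids), coordinates=coords,
                           perplexity=perplexity, seed=seed)


def correlation_matrix(
    expr: ExpressionMatrix, ids: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman correlation between cells over their gene vectors.

    Two-sided p-values per pair; Bonferroni adjustment over the
    n*(n-1)/2 pairs of the computed matrix.  Cells with constant vectors
    yield undefined (NaN) correlations and are listed in ``undefined``.
    """
    values = expr.values if ids is None else expr.values[list(ids)]
    cells = list(values.columns)
    n = len(cells)
    if n < 2:
        raise ValueError("need at least 2 cells")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 shared genes per pair")
    arr = values.to_numpy()
    res = spearmanr(arr, axis=0)  # columns (cells) are the variables
    rho = np.atleast_2d(res.statistic)
    pval = np.atleast_2d(res.pvalue)
    if rho.shape != (n, n):  # spearmanr collapses the 2-variable case
        r = float(res.statistic)
        p = float(res.pvalue)
        rho = np.array([[1.0, r], [r, 1.0]])
        pval = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    n_pairs = n * (n - 1) // 2
    p_adj = np.minimum(1.0, n_pairs * pval)
    np.fill_diagonal(p_adj, 0.0)
    const = [cells[j] for j in range(n) if np.ptp(arr[:, j]) == 0]
    return CorrelationMatrix(
        ids=cells,
        rho=pd.DataFrame(rho, index=cells, columns=cells),
        p_raw=pd.DataFrame(pval, index=cells, columns=cells),
        p_adjusted=pd.DataFrame(p_adj, index=cells, columns=cells),
        n_pairs=n_pairs,
        undefined=const,
    )
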