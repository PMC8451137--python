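"""Population-structure analysis: PCA embedding and density clustering.

Used to expose the stratification of an NC-II hybrid population (tester
half-sib families, divergent parental pools) before designing predictive
frameworks. Distances are computed on the additive 0/1/2 coding by
default — Euclidean distance between ten-state codes has no genetic
meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans, OPTICS
from sklearn.decomposition import PCA

from .geno import EncodedMatrix

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    coords: np.ndarray
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.explained_variance is not None:
            ev = np.asarray(self.explained_variance, dtype=float)
            if (np.diff(ev) > 1e-12).any() or (ev < -1e-12).any() \
                    or (ev > 1 + 1e-12).any():
                raise ValueError(
                    "explained_variance must be non-increasing fractions")
            self.explained_variance = ev


@dataclass
class ClusterResult:
    sample_ids: list[str]
    labels: np.ndarray
    ordering: np.ndarray | None = None      # OPTICS visit order
    reachability: np.ndarray | None = None  # +inf for chain starts

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.ordering is not None:
            self.ordering = np.asarray(self.ordering, dtype=int)
            if sorted(self.ordering.tolist()) != list(range(len(self.labels))):
                raise ValueError("ordering must be a permutation of samples")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0].tolist()))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Numeric matrix + ids from EncodedMatrix / EmbeddingResult / array.

    Missing genotype codes are mean-imputed per marker.
    """
    if isinstance(X, EncodedMatrix):
        M = X.to_array()
        for j in range(M.shape[1]):
            col = M[:, j]
            miss = np.isnan(col)
            if miss.any():
                col[miss] = col[~miss].mean() if (~miss).any() else 0.0
        return M, list(X.sample_ids)
    if isinstance(X, EmbeddingResult):
        return X.coords, list(X.sample_ids)
    M = np.asarray(X, dtype=float)
    return M, [str(i) for i in range(M.shape[0])]


def pca_embed(X, k: int) -> EmbeddingResult:
    """Project samples onto the top-k principal axes.

    The matrix is column-centred (after per-marker mean imputation of
    missing codes); ``explained_variance`` carries the top-k variance
    fractions from the spectrum.
    """
    M, ids = _as_matrix(X)
    n, p = M.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(M)
    return EmbeddingResult(ids, coords, pca.explained_variance_ratio_)


def optics_cluster(X, min_samples: int = 20, max_eps: float = np.inf,
                   xi: float = 0.05) -> ClusterResult:
    """OPTICS reachability ordering with xi-steepness cluster extraction.

    Noise points get label -1. The first point of each processing chain has
    infinite reachability by construction. ``min_samples > n`` degrades to
    all-noise with a warning rather than erroring.
    """
    M, ids = _as_matrix(X)
    n = M.shape[0]
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    if min_samples > n:
        logger.warning("min_samples=%d exceeds n=%d; all points are noise",
                       min_samples, n)
        return ClusterResult(ids, np.full(n, -1), np.arange(n),
                             np.full(n, np.inf))
    opt = OPTICS(min_samples=min_samples, max_eps=max_eps, xi=xi,
                 metric="euclidean")
    opt.fit(M)
    return ClusterResult(ids, opt.labels_, opt.ordering_, opt.reachability_)


def optics_dbscan_labels(result_X, min_samples: int, eps: float) -> np.ndarray:
    """DBSCAN-equivalent labels extracted from an OPTICS run at radius eps."""
    from sklearn.cluster import cluster_optics_dbscan

    M, _ = _as_matrix(result_X)
    opt = OPTICS(min_samples=min_samples, max_eps=np.inf, metric="euclidean")
    opt.fit(M)
    return cluster_optics_dbscan(
        reachability=opt.reachability_, core_distances=opt.core_distances_,
        ordering=opt.ordering_, eps=eps)


def kmeans_cluster(X, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd's algorithm with k-means++ seeding from ``seed``."""
    M, ids = _as_matrix(X)
    n = M.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=seed)
    labels = km.fit_predict(M)
    return ClusterResult(ids, labels, None, None)


def tsne_embed(X, k: int = 2, seed: int = 0, **kwargs) -> EmbeddingResult:
    """Optional t-SNE pass-through for visualisation only."""
    from sklearn.manifold import TSNE

    M, ids = _as_matrix(X)
    coords = TSNE(n_components=k, random_state=seed, **kwargs).fit_transform(M)
    return EmbeddingResult(ids, coords, None)
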