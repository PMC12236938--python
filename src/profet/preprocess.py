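"""Expression-matrix preprocessing and the shared linear latent embedding.

The trajectory machinery operates in a low-dimensional latent space; this
module provides the standard scRNA-seq-style normalization (``log(1+x)``),
pooled-variance gene selection, and a centered (covariance) PCA embedding
with an exact inverse map used to reconstruct per-gene dynamics from latent
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "SnapshotSeries",
    "LatentEmbedding",
    "log1p_normalize",
    "select_top_variance_genes",
    "fit_project",
    "project",
    "inverse_project",
]


@dataclass
class SnapshotSeries:
    """Ordered time-stamped expression matrices over a shared gene list.

    Each matrix is cells x genes; all matrices share gene count and order.
    """

    times: np.ndarray
    matrices: list[np.ndarray]
    gene_names: list[str]
    cell_ids: list[list[str]] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        if len(self.matrices) != self.times.size:
            raise ValueError("one matrix per time stamp required")
        if self.times.size == 0:
            raise ValueError("empty series")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        m = len(self.gene_names)
        for t, mat in zip(self.times, self.matrices):
            if mat.ndim != 2 or mat.shape[1] != m:
                raise ValueError(f"matrix at t={t} has wrong gene dimension")
        if self.cell_ids is None:
            self.cell_ids = [[f"t{ti}_c{j}" for j in range(mat.shape[0])]
                             for ti, mat in zip(range(self.times.size), self.matrices)]

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def pooled(self) -> np.ndarray:
        """All cells from all time points stacked into one matrix."""
        return np.vstack(self.matrices)

    def map(self, fn) -> "SnapshotSeries":
        return SnapshotSeries(times=self.times.copy(),
                              matrices=[fn(m) for m in self.matrices],
                              gene_names=list(self.gene_names),
                              cell_ids=[list(c) for c in self.cell_ids])


@dataclass
class LatentEmbedding:
    """Fitted linear (PCA) embedding: orthonormal loadings + per-gene center."""

    loadings: np.ndarray  # genes x d, orthonormal columns
    center: np.ndarray
    explained_variance_ratio: np.ndarray
    d: int

    def __post_init__(self):
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.d), atol=1e-8):
            raise ValueError("loading columns must be orthonormal")
        evr = self.explained_variance_ratio
        if (np.diff(evr) > 1e-12).any() or evr.sum() > 1 + 1e-8:
            raise ValueError("explained variance ratios must be non-increasing and sum to <= 1")


def log1p_normalize(matrix: np.ndarray) -> np.ndarray:
    """Elementwise ``log(1 + x)``; requires non-negative entries."""
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log1p(matrix)


def select_top_variance_genes(series: SnapshotSeries, k: int) -> SnapshotSeries:
    """Restrict the series to the k genes with highest pooled sample variance.

    Variance is computed across all cells pooled over time points (on the
    values as given — normalize first if desired).  Ties at the cutoff are
    broken toward the lower gene index, and the original gene order is
    preserved among the selected genes.
    """
    if not 1 <= k <= series.n_genes:
        raise ValueError(f"k={k} out of range 1..{series.n_genes}")
    var = series.pooled().var(axis=0, ddof=1)
    order = np.argsort(-var, kind="stable")  # stable: ties keep lower index first
    keep = np.sort(order[:k])
    return SnapshotSeries(times=series.times.copy(),
                          matrices=[m[:, keep] for m in series.matrices],
                          gene_names=[series.gene_names[i] for i in keep],
                          cell_ids=[list(c) for c in series.cell_ids])


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def fit_project(series: SnapshotSeries, d: int) -> tuple[LatentEmbedding, SnapshotSeries]:
    """Fit covariance PCA on all time points pooled and project the series.

    Returns the embedding and a series of latent coordinates (gene names
    replaced by component labels).  Genes are centered but not scaled.
    """
    pooled = series.pooled()
    max_d = min(pooled.shape)
    if not 1 <= d <= max_d:
        raise ValueError(f"latent dimension d={d} out of range 1..{max_d}")
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(pooled)
    loadings = _fix_signs(pca.components_.T)
    emb = LatentEmbedding(loadings=loadings, center=pca.mean_,
                          explained_variance_ratio=pca.explained_variance_ratio_, d=d)
    latent = SnapshotSeries(times=series.times.copy(),
                            matrices=[project(m, emb) for m in series.matrices],
                            gene_names=[f"PC{i + 1}" for i in range(d)],
                            cell_ids=[list(c) for c in series.cell_ids])
    return emb, latent


def project(X: np.ndarray, embedding: LatentEmbedding) -> np.ndarray:
    """Map gene-space values into latent coordinates: ``(X - center) @ loadings``."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != embedding.loadings.shape[0]:
        raise ValueError("gene dimension mismatch")
    return (X - embedding.center) @ embedding.loadings


def inverse_project(latent: np.ndarray, embedding: LatentEmbedding) -> np.ndarray:
    """Map latent coordinates back to gene space: ``latent @ loadings.T + center``.

    Applied pointwise along trailing axes, so trajectory arrays of shape
    (..., d) yield per-gene values of shape (..., genes).
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape[-1] != embedding.d:
        raise ValueError("latent dimension mismatch")
    return latent @ embedding.loadings.T + embedding.center
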