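"""Essential dynamics: Cα-covariance PCA, 2D landscapes and clustering.

The Cα positional covariance matrix of the superposed ensemble is
diagonalized; the leading eigenvectors are the essential modes and
per-frame projections onto PC1/PC2 form the conformational landscape.
Frames are clustered by k-means in the PC1–PC2 plane (K = 2 by default)
and each cluster is represented by the frame nearest its centroid —
a real sampled conformation, never a (possibly unphysical) average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from allopath.conformation import SelectionMask, calpha_mask, superpose_to_mean
from allopath.structure_io import EnsembleFrameSet

__all__ = ["PCAResult", "ClusterResult", "Landscape", "compute_pca", "project_landscape", "cluster_landscape"]


@dataclass
class PCAResult:
    """Spectral decomposition of the Cα positional covariance.

    ``eigenvalues`` (Å², descending) use the unbiased 1/(F−1)
    normalization; ``eigenvectors`` has one orthonormal column per mode
    (length 3·n_Cα); ``projections`` are centered per-frame scores.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray  # (F, n_modes)
    variance_fraction: np.ndarray
    fit_mask: str

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class Landscape:
    """Per-frame (PC1, PC2) points and a normalized 2D density histogram."""

    points: np.ndarray  # (F, 2)
    density: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


@dataclass
class ClusterResult:
    """k-means partition of frames in the PC1–PC2 plane.

    ``representatives[k]`` is the index of the frame nearest centroid k.
    ``rmsd_mean``/``rmsd_sd`` summarize a supplied per-frame RMSD series
    per cluster (None when not supplied).
    """

    labels: np.ndarray
    n_clusters: int
    representatives: np.ndarray
    centroids: np.ndarray
    rmsd_mean: np.ndarray | None = None
    rmsd_sd: np.ndarray | None = None


def compute_pca(ensemble: EnsembleFrameSet, fit_mask: SelectionMask | None = None) -> PCAResult:
    """PCA of the superposed Cα coordinates.

    Every frame is first superposed on ``fit_mask`` (all Cα by default);
    the covariance of the flattened Cα coordinates about their mean is
    then diagonalized.  Eigenvalues beyond the ensemble rank are clipped
    to zero.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    if fit_mask is None:
        fit_mask = calpha_mask(ensemble.topology)
    coords = superpose_to_mean(ensemble, fit_mask)
    ca = ensemble.topology.calpha_index
    cols = np.array([ca[int(r)] for r in ensemble.topology.residue_indices])
    x = coords[:, cols, :].reshape(ensemble.n_frames, -1)
    x = x - x.mean(axis=0)
    cov = x.T @ x / (ensemble.n_frames - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    proj = x @ v
    total = w.sum()
    frac = w / total if total > 0 else np.zeros_like(w)
    return PCAResult(eigenvalues=w, eigenvectors=v, projections=proj, variance_fraction=frac, fit_mask=fit_mask.name)


def project_landscape(pca: PCAResult, bins: int = 50) -> Landscape:
    """Project frames on (PC1, PC2) with a density histogram summing to 1."""
    if pca.projections.shape[1] < 2:
        raise ValueError("need at least two principal components")
    pts = pca.projections[:, :2]
    h, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    return Landscape(points=pts, density=h / h.sum(), x_edges=xe, y_edges=ye)


def cluster_landscape(
    pca: PCAResult, n_clusters: int = 2, seed: int = 0, rmsd_values: np.ndarray | None = None
) -> ClusterResult:
    """Seeded multi-start k-means on the (PC1, PC2) projections."""
    f = pca.projections.shape[0]
    if not 1 <= n_clusters <= f:
        raise ValueError(f"cluster count {n_clusters} outside 1..{f}")
    pts = pca.projections[:, : min(2, pca.projections.shape[1])]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pts)
    labels = km.labels_
    reps = np.empty(n_clusters, dtype=int)
    for k in range(n_clusters):
        members = np.flatnonzero(labels == k)
        d = np.linalg.norm(pts[members] - km.cluster_centers_[k], axis=1)
        reps[k] = members[np.argmin(d)]
    rmsd_mean = rmsd_sd = None
    if rmsd_values is not None:
        rmsd_values = np.asarray(rmsd_values, float)
        rmsd_mean = np.array([rmsd_values[labels == k].mean() for k in range(n_clusters)])
        rmsd_sd = np.array([rmsd_values[labels == k].std() for k in range(n_clusters)])
    return ClusterResult(
        labels=labels, n_clusters=n_clusters, representatives=reps,
        centroids=km.cluster_centers_, rmsd_mean=rmsd_mean, rmsd_sd=rmsd_sd,
    )
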