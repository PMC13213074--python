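"""Principal component analysis of trajectory feature matrices.

Covariance PCA of a frames x features matrix (features mean-centered
internally), plus extraction of a representative frame from the most
populated region of the PC1/PC2 plane: the densest bin of a 2D histogram
is located and the frame closest to its center is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "pca_fit", "representative_frame"]


@dataclass
class PCAResult:
    """Eigendecomposition of the feature covariance.

    ``components`` rows are orthonormal eigenvectors in descending
    eigenvalue order with a deterministic sign convention (the
    largest-magnitude loading of each component is positive);
    ``projections`` are the centered data projected onto every component.
    """

    components: np.ndarray         # (n_components, n_features)
    eigenvalues: np.ndarray        # descending, >= 0
    explained_variance_ratio: np.ndarray
    projections: np.ndarray        # (n_frames, n_components)
    mean: np.ndarray               # feature means removed before the fit

    @property
    def pc12(self) -> np.ndarray:
        """Projections onto PC1/PC2 (second column zero-padded if absent)."""
        if self.projections.shape[1] >= 2:
            return self.projections[:, :2]
        return np.column_stack([self.projections[:, 0],
                                np.zeros(len(self.projections))])


def pca_fit(feature_matrix) -> PCAResult:
    """Covariance PCA of a frames x features matrix.

    Zero-variance input yields all-zero eigenvalues and projections (the
    explained-variance ratio is reported as zero in that degenerate case).
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2D (frames x features)")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 frames")
    if p < 1:
        raise ValueError("PCA requires at least 1 feature")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    ratio = eigvals / total if total > 0 else np.zeros_like(eigvals)
    projections = Xc @ eigvecs
    return PCAResult(components=eigvecs.T, eigenvalues=eigvals,
                     explained_variance_ratio=ratio, projections=projections,
                     mean=mean)


def representative_frame(projections, n_bins: int = 50) -> int:
    """Frame index representing the densest region of the PC1/PC2 plane.

    A 2D histogram of the first two projection columns is built; the bin
    with the highest count is selected (ties broken by smaller
    row-major ``(i, j)`` index), and the frame minimizing the Euclidean
    distance to that bin's center is returned (ties by earliest frame).
    """
    P = np.atleast_2d(np.asarray(projections, dtype=float))
    if P.shape[0] == 1 and P.shape[1] > 2:
        P = P.T
    if P.shape[0] == 0:
        raise ValueError("no frames to select from")
    if P.shape[1] == 1:
        P = np.column_stack([P[:, 0], np.zeros(P.shape[0])])
    xy = P[:, :2]
    counts, ex, ey = np.histogram2d(xy[:, 0], xy[:, 1], bins=n_bins)
    i, j = np.unravel_index(int(np.argmax(counts)), counts.shape)
    center = np.array([0.5 * (ex[i] + ex[i + 1]), 0.5 * (ey[j] + ey[j + 1])])
    dist2 = ((xy - center) ** 2).sum(axis=1)
    return int(np.argmin(dist2))
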