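"""Independent brute-force oracles shared by the PCA tests."""

import numpy as np
import scipy.linalg


def brute_force_pca_eigenvalues(X):
    """Explicit covariance accumulation + symmetric eigendecomposition."""
    n, p = X.shape
    mean = [sum(X[i, j] for i in range(n)) / n for j in range(p)]
    cov = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            cov[a, b] = sum(
                (X[i, a] - mean[a]) * (X[i, b] - mean[b]) for i in range(n)
            ) / (n - 1)
    return np.sort(scipy.linalg.eigvalsh(cov))[::-1]


def brute_force_densest_bin_frame(xy, n_bins):
    """Explicit bin counting and distance scan over the PC1/PC2 plane."""
    x, y = xy[:, 0], xy[:, 1]
    ex = np.linspace(x.min(), x.max(), n_bins + 1)
    ey = np.linspace(y.min(), y.max(), n_bins + 1)
    best = (-1, None, None)
    for i in range(n_bins):
        for j in range(n_bins):
            hi_x = x <= ex[i + 1] if i == n_bins - 1 else x < ex[i + 1]
            hi_y = y <= ey[j + 1] if j == n_bins - 1 else y < ey[j + 1]
            count = int(((x >= ex[i]) & hi_x & (y >= ey[j]) & hi_y).sum())
            if count > best[0]:
                best = (count, i, j)
    _, i, j = best
    center = np.array([(ex[i] + ex[i + 1]) / 2, (ey[j] + ey[j + 1]) / 2])
    d = np.sqrt(((xy - center) ** 2).sum(axis=1))
    return int(np.argmin(d))
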