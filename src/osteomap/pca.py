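"""Principal component analysis for shape, form and bone-modelling data.

space="shape": columns are flattened aligned Procrustes coordinates.
space="form":  one extra column, the natural log of centroid size, is
               appended (Procrustes form space).
space="bm":    columns are per-square percent bone resorption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCAResult:
    space: str
    scores: np.ndarray             # n x m
    loadings: np.ndarray           # p x m variable axes (columns orthonormal)
    eigenvalues: np.ndarray        # m, non-increasing
    variance_fractions: np.ndarray  # m, sums to 1
    mean: np.ndarray               # p column means

    def reconstruct(self) -> np.ndarray:
        """Centred data reconstructed from scores and loadings."""
        return self.scores @ self.loadings.T


def pca(data: np.ndarray, space: str = "shape",
        centroid_sizes: np.ndarray | None = None) -> PCAResult:
    """PCA by singular value decomposition of the column-centred data.

    Eigenvalues are sample covariance eigenvalues (divisor n-1) and the sign
    of each component is fixed so its largest-magnitude loading is positive,
    making results independent of specimen order.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 3:  # n x K x 3 aligned shapes
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError("data must be an n x p matrix (or n x K x 3 shapes)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    if space == "form":
        if centroid_sizes is None:
            raise ValueError("form space requires centroid sizes")
        cs = np.asarray(centroid_sizes, dtype=float)
        if np.any(cs <= 0):
            raise ValueError("centroid sizes must be positive")
        X = np.hstack([X, np.log(cs)[:, None]])

    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 0):
        raise ValueError("constant data matrix has no principal components")

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = min(n - 1, Xc.shape[1])
    U, s, Vt = U[:, :m], s[:m], Vt[:m]
    # fix component signs: largest-magnitude loading positive
    flips = np.sign(Vt[np.arange(m), np.argmax(np.abs(Vt), axis=1)])
    flips[flips == 0] = 1.0
    Vt = Vt * flips[:, None]
    U = U * flips[None, :]

    eigenvalues = s ** 2 / (n - 1)
    total = eigenvalues.sum()
    return PCAResult(space=space, scores=U * s, loadings=Vt.T,
                     eigenvalues=eigenvalues,
                     variance_fractions=eigenvalues / total, mean=mean)
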