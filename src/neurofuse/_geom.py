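"""Shared 3D geometry helpers: PCA canonicalization of point clouds."""

from __future__ import annotations

import numpy as np

__all__ = ["pca_canonical_frame", "pca_canonicalize"]

_SKEW_TIE_TOL = 1e-6


def pca_canonical_frame(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and rotation matrix of the PCA-canonical frame of a point cloud.

    Axes are the principal components in descending-variance order.  The sign
    of each axis is fixed deterministically: the standardized third moment
    (skewness) of the projected coordinates must be non-negative; on a tie
    (|skew| below tolerance) the coordinate of the point farthest from the
    centroid must be non-negative.

    Returns ``(centroid, R)`` with canonical coordinates ``(xyz - centroid) @ R``.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    centroid = xyz.mean(axis=0)
    X = xyz - centroid
    n = X.shape[0]
    if n == 1:
        return centroid, np.eye(3)
    cov = (X.T @ X) / n
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    R = evecs[:, order]
    Y = X @ R
    far = int(np.argmax(np.einsum("ij,ij->i", X, X)))
    for j in range(3):
        col = Y[:, j]
        sd = col.std()
        skew = float(np.mean(col**3) / sd**3) if sd > 0 else 0.0
        if abs(skew) > _SKEW_TIE_TOL:
            flip = skew < 0
        else:
            flip = col[far] < 0
        if flip:
            R[:, j] = -R[:, j]
            Y[:, j] = -Y[:, j]
    return centroid, R


def pca_canonicalize(xyz: np.ndarray) -> np.ndarray:
    """Point cloud expressed in its PCA-canonical frame."""
    centroid, R = pca_canonical_frame(xyz)
    return (np.asarray(xyz, dtype=float) - centroid) @ R
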