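"""Crystal coordinates from pairwise transit-time distances.

Sonomicrometry measures inter-crystal distances; 3D positions are recovered
by classical multidimensional scaling (Torgerson), which is exact for
noise-free Euclidean distances and least-squares optimal otherwise.  The
embedding is unique only up to rigid motion and reflection, so successive
frames are aligned to their predecessor by orthogonal Procrustes to suppress
arbitrary rotation/reflection flips between frames.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes

__all__ = [
    "DistanceMatrixError",
    "DegenerateEmbeddingError",
    "classical_mds",
    "coordinates_from_distances",
    "pairwise_distances",
    "aligned_rmsd",
]


class DistanceMatrixError(ValueError):
    """Input matrix is not a valid symmetric distance matrix."""


class DegenerateEmbeddingError(ValueError):
    """Distance matrix does not support a full-rank 3D embedding."""


def _validate(D: np.ndarray, atol: float) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DistanceMatrixError(f"distance matrix must be square, got {D.shape}")
    n = D.shape[0]
    if n < 4:
        raise DistanceMatrixError(f"need at least 4 crystals for a 3D embedding, got {n}")
    scale = max(float(np.max(np.abs(D))), 1.0)
    if not np.allclose(D, D.T, atol=atol * scale):
        raise DistanceMatrixError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=atol * scale):
        raise DistanceMatrixError("distance matrix diagonal is not zero")
    return 0.5 * (D + D.T)


def classical_mds(D: np.ndarray, ndim: int = 3, atol: float = 1e-8) -> np.ndarray:
    """Torgerson MDS embedding of one distance matrix into ``ndim`` dims.

    Returns centred coordinates (n, ndim).  Raises
    :class:`DegenerateEmbeddingError` when the double-centred Gram matrix has
    rank below ``ndim`` (e.g. all crystals coplanar for ndim=3 would still be
    rank >= 2 but not 3).
    """
    D = _validate(D, atol)
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[ndim - 1] <= 1e-10 * max(evals[0], 1.0):
        raise DegenerateEmbeddingError(
            f"embedding rank < {ndim}: crystal configuration is degenerate"
        )
    lam = np.clip(evals[:ndim], 0.0, None)
    return evecs[:, :ndim] * np.sqrt(lam)


def coordinates_from_distances(
    dist_matrices: np.ndarray, atol: float = 1e-8
) -> np.ndarray:
    """Crystal trajectories from per-frame distance matrices.

    Parameters
    ----------
    dist_matrices : (T, N, N) or (N, N) array
        Symmetric pairwise inter-crystal distances (mm) per time sample.

    Returns
    -------
    (T, N, 3) (or (N, 3)) centred coordinates; each frame after the first is
    rotated/reflected onto its predecessor (orthogonal Procrustes) so the
    reconstructed motion is temporally coherent.
    """
    D = np.asarray(dist_matrices, dtype=float)
    single = D.ndim == 2
    if single:
        D = D[None]
    coords = np.empty((D.shape[0], D.shape[1], 3))
    prev: np.ndarray | None = None
    for t in range(D.shape[0]):
        X = classical_mds(D[t], ndim=3, atol=atol)
        if prev is not None:
            R, _ = orthogonal_procrustes(X, prev)
            X = X @ R
        coords[t] = X
        prev = X
    return coords[0] if single else coords


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix/matrices of (.., N, 3) coordinates."""
    X = np.asarray(X, dtype=float)
    diff = X[..., :, None, :] - X[..., None, :, :]
    return np.linalg.norm(diff, axis=-1)


def aligned_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD between two configurations after optimal rigid alignment.

    Translation, rotation and reflection are removed (Kabsch/Procrustes with
    reflections allowed), matching the inherent ambiguity of an MDS embedding.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R, _ = orthogonal_procrustes(Xc, Yc)
    return float(np.sqrt(np.mean(np.sum((Xc @ R - Yc) ** 2, axis=1))))
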