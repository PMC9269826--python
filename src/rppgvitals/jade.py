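"""JADE blind source separation for real-valued signals.

Joint Approximate Diagonalisation of Eigen-matrices: whiten the observations,
estimate a parallel set of fourth-order cumulant matrices, and jointly
diagonalise them with Givens rotations.  Separates up to permutation, sign and
scale, like any ICA.  Implemented here because no installed package ships it;
validated in the test suite against a known two-source mixture.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def _whiten(X: np.ndarray, m: int):
    """PCA whitening: returns whitened signals Z (m x T) and the whitener W."""
    cov = np.cov(X)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:m]
    d = eigval[order]
    d = np.maximum(d, np.finfo(float).tiny)
    W = (eigvec[:, order] / np.sqrt(d)).T  # m x n
    return W @ X, W


def _cumulant_matrices(Z: np.ndarray) -> np.ndarray:
    """Parallel set of m(m+1)/2 fourth-order cumulant matrices, stacked (k, m, m)."""
    m, T = Z.shape
    eye = np.eye(m)
    mats = []
    for i in range(m):
        for j in range(i + 1):
            zij = Z[i] * Z[j]
            Q = (Z * zij) @ Z.T / T
            Q -= eye * (1.0 if i == j else 0.0)
            Q[i, j] -= 1.0
            Q[j, i] -= 1.0
            # scale off-diagonal estimates by sqrt(2) as in the reference algorithm
            mats.append(Q if i == j else Q * np.sqrt(2.0))
    return np.array(mats)


def _joint_diagonalise(mats: np.ndarray, tol: float = 1e-8, max_sweeps: int = 100):
    """Jacobi joint diagonalisation; returns the orthogonal rotation V (m x m)."""
    k, m, _ = mats.shape
    V = np.eye(m)
    A = mats.copy()
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                g = np.stack([A[:, p, p] - A[:, q, q], A[:, p, q] + A[:, q, p]])
                gg = g @ g.T
                ton = gg[0, 0] - gg[1, 1]
                toff = gg[0, 1] + gg[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                if abs(np.sin(theta)) <= tol:
                    continue
                rotated = True
                c, s = np.cos(theta), np.sin(theta)
                rot = np.array([[c, -s], [s, c]])
                A[:, :, [p, q]] = A[:, :, [p, q]] @ rot
                A[:, [p, q], :] = np.einsum("ij,kjl->kil", rot.T, A[:, [p, q], :])
                V[:, [p, q]] = V[:, [p, q]] @ rot
        if not rotated:
            break
    return V


def jade(X, n_components: int | None = None) -> np.ndarray:
    """Extract independent components from an (n x T) observation matrix.

    Returns an (m x T) array of source estimates, where m defaults to n.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("JADE expects a 2-D (signals x samples) matrix")
    n, T = X.shape
    if T <= n:
        raise ValidationError("need more samples than signals")
    m = n_components or n
    Xc = X - X.mean(axis=1, keepdims=True)
    Z, W = _whiten(Xc, m)
    mats = _cumulant_matrices(Z)
    V = _joint_diagonalise(mats)
    return V.T @ Z
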