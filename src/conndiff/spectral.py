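"""Projector decomposition of covariance matrices.

Any symmetric matrix is the eigenvalue-weighted sum of the rank-1
projectors ``P_i = |u_i><u_i|`` built from its orthonormal eigenvectors.
Under the linear model SC and its stationary covariance share
eigenvectors — only the projector weights differ — which makes the
fixed eigenbasis of the total covariance a natural coordinate system for
sliding-window covariances: each window splits exactly into a projector
part (diagonal coefficients in the basis) and a mixed part (off-diagonal
dyads ``|u_i><u_j|``, i != j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .network import TimeSeriesData
from .windows import WindowSpec, window_covariances

__all__ = [
    "ProjectorDecomposition",
    "WindowDecomposition",
    "projector_set",
    "window_decomposition",
    "reduced_covariance",
    "goodness_of_fit",
    "subspace_similarity",
]


@dataclass(frozen=True)
class ProjectorDecomposition:
    """Eigenbasis of a symmetric matrix with its rank-1 projectors.

    Eigenvalues are sorted descending; each eigenvector's sign is fixed
    by making its largest-magnitude component positive so the basis is
    deterministic.
    """

    eigenvalues: np.ndarray  # (n,), descending
    eigenvectors: np.ndarray  # (n, n), columns |u_i>

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    def projector(self, i: int) -> np.ndarray:
        u = self.eigenvectors[:, i]
        return np.outer(u, u)

    @property
    def projectors(self) -> np.ndarray:
        """All rank-1 projectors, shape (n, n, n)."""
        U = self.eigenvectors
        return np.einsum("ik,jk->kij", U, U)

    def reconstruct(self) -> np.ndarray:
        U, mu = self.eigenvectors, self.eigenvalues
        return (U * mu) @ U.T


def _fix_signs(U: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def projector_set(matrix: np.ndarray) -> ProjectorDecomposition:
    """Orthonormal eigenbasis and projectors of a symmetric matrix."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(M, M.T, rtol=1e-10, atol=1e-12):
        raise ValueError("projector decomposition requires a symmetric matrix")
    mu, U = linalg.eigh(M)
    order = np.argsort(mu)[::-1]  # descending; ties keep original order (stable)
    mu = mu[order]
    U = _fix_signs(U[:, order])
    return ProjectorDecomposition(eigenvalues=mu, eigenvectors=U)


@dataclass(frozen=True)
class WindowDecomposition:
    """Per-window covariance coefficients in a fixed eigenbasis.

    ``projector_coeffs[k, i]`` weights projector i in window k (the
    diagonal of the basis-rotated window covariance); ``mixed_coeffs[k]``
    holds the off-diagonal (dyadic) coefficients with a zero diagonal.
    ``b_coeffs[k]`` are the per-window projections b_i(t) = <u_i|x(t)>.
    """

    projector_coeffs: np.ndarray  # (n_windows, n)
    mixed_coeffs: np.ndarray  # (n_windows, n, n), zero diagonal
    b_coeffs: tuple[np.ndarray, ...]  # each (w, n)


def window_decomposition(
    ts: TimeSeriesData, spec: WindowSpec, basis: ProjectorDecomposition
) -> WindowDecomposition:
    """Decompose each window covariance over a fixed eigenbasis.

    The coefficients are the entries of ``U^T C_w U``; completeness makes
    the reconstruction from projector plus mixed terms exact.
    """
    if basis.n != ts.n_regions:
        raise ValueError("basis dimension does not match the time series")
    U = basis.eigenvectors
    covs = window_covariances(ts, spec)
    n_win = covs.shape[0]
    proj = np.empty((n_win, basis.n))
    mixed = np.empty((n_win, basis.n, basis.n))
    bs = []
    X = ts.values
    w = spec.length_samples
    for k in range(n_win):
        M = U.T @ covs[k] @ U
        proj[k] = np.diag(M)
        off = M.copy()
        np.fill_diagonal(off, 0.0)
        mixed[k] = off
        seg = X[spec.starts[k] : spec.starts[k] + w]
        bs.append(seg @ U)
    return WindowDecomposition(
        projector_coeffs=proj, mixed_coeffs=mixed, b_coeffs=tuple(bs)
    )


def reduced_covariance(
    decomp: WindowDecomposition, basis: ProjectorDecomposition, k: int
) -> np.ndarray:
    """Per-window covariance rebuilt from the top-k projectors and the
    k(k-1)/2 mixed terms among the top-k eigenvectors.

    Returns shape (n_windows, n, n); with k = n the reconstruction is the
    exact window covariance.
    """
    n = basis.n
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    Uk = basis.eigenvectors[:, :k]
    n_win = decomp.projector_coeffs.shape[0]
    out = np.empty((n_win, n, n))
    for w in range(n_win):
        M = decomp.mixed_coeffs[w][:k, :k].copy()
        np.fill_diagonal(M, decomp.projector_coeffs[w][:k])
        out[w] = Uk @ M @ Uk.T
    return out


def goodness_of_fit(
    ts: TimeSeriesData, basis: ProjectorDecomposition, k: int
) -> float:
    """Fraction of signal variance captured by the top-k eigenvectors.

    The mean-centered series is projected onto the leading k basis
    vectors; the score is ``1 - ||X - X_proj||_F^2 / ||X||_F^2``
    (variance accounted for).  Monotone non-decreasing in k; 0 at k = 0
    and 1 at k = n.
    """
    if not 0 <= k <= basis.n:
        raise ValueError(f"k must lie in [0, {basis.n}]")
    if basis.n != ts.n_regions:
        raise ValueError("basis dimension does not match the time series")
    X = ts.values - ts.values.mean(axis=0)
    total = float(np.sum(X**2))
    if total == 0:
        raise ValueError("constant series: goodness of fit undefined")
    if k == 0:
        return 0.0
    Uk = basis.eigenvectors[:, :k]
    resid = X - (X @ Uk) @ Uk.T
    return float(1.0 - np.sum(resid**2) / total)


def subspace_similarity(basis_a: np.ndarray, basis_b: np.ndarray,
                        aggregate: str = "mean") -> float:
    """Similarity of two k-dimensional subspaces via principal angles.

    The singular values of ``A^T B`` (orthonormal columns) are the
    cosines of the principal angles.  For 1-D subspaces this is the
    absolute scalar product.  ``aggregate`` chooses the summary across
    angles: "mean" of the cosines (default) or "first" (largest).
    Returns 1 for identical subspaces and 0 for orthogonal ones.
    """
    A = np.atleast_2d(np.asarray(basis_a, dtype=float))
    B = np.atleast_2d(np.asarray(basis_b, dtype=float))
    if A.ndim != 2 or B.ndim != 2 or A.shape != B.shape:
        raise ValueError("bases must be (n, k) matrices of equal shape")
    if A.shape[0] < A.shape[1]:
        raise ValueError("bases must have at least as many rows as columns")
    for name, Q in (("basis_a", A), ("basis_b", B)):
        G = Q.T @ Q
        if not np.allclose(G, np.eye(Q.shape[1]), atol=1e-8):
            raise ValueError(f"{name} does not have orthonormal columns")
    svals = linalg.svd(A.T @ B, compute_uv=False)
    svals = np.clip(svals, 0.0, 1.0)
    if aggregate == "mean":
        return float(svals.mean())
    if aggregate == "first":
        return float(svals[0])
    raise ValueError(f"unknown aggregate {aggregate!r}")
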