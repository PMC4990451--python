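"""Forward operator: stationary covariance of linear noise diffusion.

The model is a multivariate Ornstein-Uhlenbeck process

    dx = A x dt + sigma dxi,    A = -I + c W,

whose stationary covariance, for symmetric W and uniform noise, has the
closed form

    C = -(sigma^2 / 2) A^{-1}.

The Pearson correlation derived from C is the analytically predicted
functional connectivity (aFC).  For asymmetric A the exact stationary
covariance solves the continuous Lyapunov equation
``A C + C A^T = -Sigma``; a truncated Baker-Campbell-Hausdorff (BCH)
combination of the two propagator exponentials is provided as the
series counterpart.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .network import (
    CONDITION_LIMIT,
    STABILITY_MARGIN,
    CouplingSpec,
    NoiseSpec,
    StructuralNetwork,
    UnstableRegimeError,
)

__all__ = [
    "critical_coupling",
    "coupling_matrix",
    "analytic_covariance",
    "stationary_covariance_general",
    "covariance_to_correlation",
    "small_c_covariance",
    "analytic_fc",
]


def critical_coupling(net: StructuralNetwork) -> CouplingSpec:
    """Stability boundary of the linear model on this network.

    ``c_critic = 1 / max_i lambda_i`` with ``lambda_i`` the eigenvalues of
    W (real parts for asymmetric W).  Raises if no eigenvalue is positive,
    in which case the model is stable for every ``c >= 0`` and there is no
    finite boundary.
    """
    W = net.weights
    if net.is_symmetric:
        eigvals = linalg.eigvalsh(W)
    else:
        eigvals = np.real(linalg.eigvals(W))
    eigvals = np.sort(eigvals)[::-1]
    lam_max = eigvals[0]
    if lam_max <= 0:
        raise ValueError(
            "no finite stability boundary: largest eigenvalue of W is not positive"
        )
    return CouplingSpec(c_critic=1.0 / lam_max, eigenvalues_W=eigvals)


def _check_stable(net: StructuralNetwork, c: float) -> CouplingSpec | None:
    if c < 0:
        raise ValueError("global coupling c must be nonnegative")
    try:
        spec = critical_coupling(net)
    except ValueError:
        # no positive eigenvalue: stable for every nonnegative coupling
        return None
    if c >= spec.c_critic * (1.0 - STABILITY_MARGIN):
        raise UnstableRegimeError(
            f"unstable regime: c={c:g} >= c_critic={spec.c_critic:g}; "
            "the equilibrium of the linear model is not stable"
        )
    return spec


def coupling_matrix(net: StructuralNetwork, c: float) -> np.ndarray:
    """The drift matrix ``A = -I + c W``."""
    n = net.n_regions
    return -np.eye(n) + c * net.weights


def _solve_inverse(M: np.ndarray, what: str) -> np.ndarray:
    """Invert via a linear solve against the identity; reject ill-conditioned input."""
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"{what} is singular or near-singular (condition number {cond:.3g})"
        )
    return linalg.solve(M, np.eye(M.shape[0]))


def analytic_covariance(
    net: StructuralNetwork, c: float, noise: NoiseSpec | float = 1.0
) -> np.ndarray:
    """Stationary covariance ``C = -(sigma^2/2) (-I + cW)^{-1}``.

    Requires symmetric W and ``c`` strictly below the critical coupling.
    With per-node noise the uniform-sigma formula generalizes to
    ``C = -(1/2) A^{-1} Sigma`` when A and Sigma commute; otherwise the
    exact Lyapunov solution is used.
    """
    if isinstance(noise, (int, float)):
        noise = NoiseSpec(noise)
    if not net.is_symmetric:
        raise ValueError(
            "analytic_covariance requires symmetric W; use "
            "stationary_covariance_general for asymmetric drift matrices"
        )
    _check_stable(net, c)
    A = coupling_matrix(net, c)
    A_inv = _solve_inverse(A, "coupling matrix A")
    if noise.is_uniform:
        C = -(float(noise.sigma) ** 2 / 2.0) * A_inv
    else:
        Sigma = noise.Sigma(net.n_regions)
        if np.allclose(A @ Sigma, Sigma @ A, rtol=1e-12, atol=1e-12):
            C = -0.5 * A_inv @ Sigma
        else:
            C = linalg.solve_continuous_lyapunov(A, -Sigma)
    return 0.5 * (C + C.T)


def _bch_Z(A: np.ndarray, order: int) -> np.ndarray:
    """Truncated BCH combination of exp(tA) exp(tA^T) = exp(tZ).

    ``order`` counts nested commutator levels: 0 keeps ``A + A^T``,
    1 adds ``[A, A^T]``, 2 adds ``([A,[A,A^T]] - [A^T,[A,A^T]]) / 2``.
    For symmetric A every commutator vanishes and Z = 2A exactly.
    """
    if order < 0:
        raise ValueError("bch_order must be >= 0")
    At = A.T
    Z = A + At
    if order >= 1:
        comm1 = A @ At - At @ A
        Z = Z + comm1
        if order >= 2:
            Z = Z + 0.5 * ((A @ comm1 - comm1 @ A) - (At @ comm1 - comm1 @ At))
        if order >= 3:
            raise NotImplementedError("BCH truncation beyond 2 commutator levels")
    return Z


def stationary_covariance_general(
    A: np.ndarray,
    noise: NoiseSpec | float = 1.0,
    mode: str = "lyapunov",
    bch_order: int = 2,
) -> np.ndarray:
    """Stationary covariance for a general stable drift matrix A.

    mode="lyapunov" solves ``A C + C A^T = -Sigma`` exactly (the
    long-time limit of the OU propagator integral); mode="bch" evaluates
    ``C = -sigma^2 Z^{-1}`` with Z the truncated BCH combination of A and
    A^T, which is exact for normal A and an uncontrolled approximation
    otherwise.  Both reduce to ``-(sigma^2/2) A^{-1}`` for symmetric A.
    """
    if isinstance(noise, (int, float)):
        noise = NoiseSpec(noise)
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    eig_real = np.real(linalg.eigvals(A))
    if np.any(eig_real >= 0):
        raise UnstableRegimeError(
            "unstable drift matrix: all eigenvalues of A must have negative real part"
        )
    Sigma = noise.Sigma(n)
    if mode == "lyapunov":
        C = linalg.solve_continuous_lyapunov(A, -Sigma)
    elif mode == "bch":
        if not noise.is_uniform:
            raise ValueError("bch mode supports uniform sigma only")
        Z = _bch_Z(A, bch_order)
        Z_inv = _solve_inverse(Z, "BCH matrix Z")
        C = -float(noise.sigma) ** 2 * Z_inv
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'lyapunov' or 'bch'")
    return 0.5 * (C + C.T)


def covariance_to_correlation(C: np.ndarray) -> np.ndarray:
    """Pearson correlation ``R_ij = C_ij / sqrt(C_ii C_jj)``."""
    C = np.asarray(C, dtype=float)
    d = np.diag(C)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive variance at node(s) {bad.tolist()}: cannot normalize"
        )
    s = np.sqrt(d)
    R = C / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return R


def small_c_covariance(
    net: StructuralNetwork, c: float, noise: NoiseSpec | float = 1.0
) -> np.ndarray:
    """First-order covariance ``(sigma^2/2)(I + cW)`` for small coupling.

    The exact covariance Taylor-expanded around c = 0: the structural
    matrix appears added to the identity, so weak-coupling correlations
    directly mirror structure.  The truncation error is O(c^2).
    """
    if isinstance(noise, (int, float)):
        noise = NoiseSpec(noise)
    if not net.is_symmetric:
        raise ValueError("small_c_covariance requires symmetric W")
    if c < 0:
        raise ValueError("c must be nonnegative")
    if not noise.is_uniform:
        raise ValueError("small-c expansion is stated for uniform sigma")
    n = net.n_regions
    return (float(noise.sigma) ** 2 / 2.0) * (np.eye(n) + c * net.weights)


def analytic_fc(
    net: StructuralNetwork, c: float, noise: NoiseSpec | float = 1.0
) -> np.ndarray:
    """Analytically predicted FC (correlation of the stationary covariance)."""
    return covariance_to_correlation(analytic_covariance(net, c, noise))
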