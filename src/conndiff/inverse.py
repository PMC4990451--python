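"""Inverse operator: recover structure from a covariance matrix.

Inverting the stationary-covariance formula of the linear model gives

    W_{i!=j} = -(sigma^2 / 2c) (C^{-1})_{i!=j}

so the structural matrix is, up to a positive scale, minus the
off-diagonal inverse covariance — equivalently, a rescaled partial
correlation.  Both model parameters act as pure scale factors, so the
inferred structure needs no parameter fitting when only relative weights
matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .network import CONDITION_LIMIT, NoiseSpec, SingularCovarianceError

__all__ = [
    "InverseResult",
    "analytic_sc",
    "partial_correlation",
    "estimate_sigma",
    "estimate_sigma_per_node",
    "DEFAULT_C",
    "DEFAULT_SIGMA",
]

# With (c, sigma) = (1, sqrt(2)) the inverse operator reduces to -C^{-1}
# with zeroed diagonal; only relative structure is meaningful.
DEFAULT_C = 1.0
DEFAULT_SIGMA = float(np.sqrt(2.0))


@dataclass(frozen=True)
class InverseResult:
    """Analytically inferred structural matrix plus bookkeeping.

    ``W_hat`` has an exactly zero diagonal (the diagonal of the inverse
    covariance only encodes the noise variance, not structure).  When
    negative entries are clipped their count, mean and SD are recorded
    before zeroing.  ``sigma_hat`` is the noise amplitude implied by
    ``diag(C^{-1}) = 2 / sigma^2``.
    """

    W_hat: np.ndarray
    n_negative: int
    negative_mean: float
    negative_sd: float
    sigma_hat: float
    clipped: bool


def _inverse_covariance(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be a square matrix")
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularCovarianceError(
            f"covariance not invertible (condition number {cond:.3g}); note that "
            "global-signal-regressed data introduce zero eigenvalues and are "
            "invalid inputs for the inverse operation"
        )
    return linalg.solve(C, np.eye(C.shape[0]), assume_a="sym")


def analytic_sc(
    C: np.ndarray,
    c: float = DEFAULT_C,
    noise: NoiseSpec | float = DEFAULT_SIGMA,
    clip_negative: bool = False,
    symmetrize: bool = False,
) -> InverseResult:
    """Infer structure: ``W_hat = -(sigma^2/2c) C^{-1}`` off the diagonal.

    Parameters
    ----------
    C
        Symmetric invertible covariance matrix (use covariance, not
        correlation, when absolute scale matters).
    c, noise
        Model parameters; both act purely as positive scale factors on
        the result.  Defaults give ``W_hat = -C^{-1}`` off-diagonal.
    clip_negative
        Zero out negative inferred weights (they have no meaning as
        structural connections); statistics of the removed entries are
        reported.  Leave off for exact round trips.
    symmetrize
        Accept a (slightly) asymmetric C by averaging with its transpose.
        Off by default: the inverse operation is only valid for
        symmetric input.
    """
    if isinstance(noise, (int, float)):
        noise = NoiseSpec(noise)
    if not noise.is_uniform:
        raise ValueError("the inverse operation assumes uniform sigma")
    if c <= 0:
        raise ValueError("c must be strictly positive")
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, rtol=1e-8, atol=1e-12):
        if symmetrize:
            C = 0.5 * (C + C.T)
        else:
            raise ValueError(
                "covariance is asymmetric; the inverse operation is only valid "
                "for symmetric input (pass symmetrize=True to average C and C^T)"
            )
    P = _inverse_covariance(C)
    sigma_hat = estimate_sigma(C, precision=P)
    W_hat = -(float(noise.sigma) ** 2 / (2.0 * c)) * P
    np.fill_diagonal(W_hat, 0.0)
    W_hat = 0.5 * (W_hat + W_hat.T)

    off = ~np.eye(C.shape[0], dtype=bool)
    neg = W_hat[off & (W_hat < 0)]
    n_negative = int(neg.size)
    negative_mean = float(neg.mean()) if n_negative else 0.0
    negative_sd = float(neg.std()) if n_negative else 0.0
    if clip_negative:
        W_hat = np.where(W_hat < 0, 0.0, W_hat)
    return InverseResult(
        W_hat=W_hat,
        n_negative=n_negative,
        negative_mean=negative_mean,
        negative_sd=negative_sd,
        sigma_hat=sigma_hat,
        clipped=clip_negative,
    )


def partial_correlation(C: np.ndarray) -> np.ndarray:
    """Partial correlation ``Pi_ij = -C^{-1}_ij / sqrt(C^{-1}_ii C^{-1}_jj)``.

    Under the linear model with uniform noise this is proportional to the
    inferred structure off the diagonal: partial correlation IS the
    (rescaled) structural matrix.
    """
    P = _inverse_covariance(np.asarray(C, dtype=float))
    d = np.diag(P)
    if np.any(d <= 0):
        raise SingularCovarianceError(
            "inverse covariance has nonpositive diagonal entries"
        )
    s = np.sqrt(d)
    Pi = -P / np.outer(s, s)
    np.fill_diagonal(Pi, 1.0)
    return 0.5 * (Pi + Pi.T)


def estimate_sigma(C: np.ndarray, precision: np.ndarray | None = None) -> float:
    """Noise amplitude from ``diag(C^{-1}) = 2/sigma^2``.

    For covariances generated by the forward operator with uniform sigma
    the per-node values coincide and the estimate is exact; for empirical
    input the mean of the precision diagonal is used.
    """
    P = _inverse_covariance(C) if precision is None else precision
    d = np.diag(P)
    if np.any(d <= 0):
        raise SingularCovarianceError(
            "inverse covariance has nonpositive diagonal entries"
        )
    return float(np.sqrt(2.0 / d.mean()))


def estimate_sigma_per_node(C: np.ndarray) -> np.ndarray:
    """Per-node noise estimates ``sqrt(2 / C^{-1}_ii)`` (spread diagnostic)."""
    P = _inverse_covariance(C)
    d = np.diag(P)
    if np.any(d <= 0):
        raise SingularCovarianceError(
            "inverse covariance has nonpositive diagonal entries"
        )
    return np.sqrt(2.0 / d)
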