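"""Core domain containers for structural networks, noise, and covariance.

A structural connectivity (SC) matrix holds nonnegative coupling weights
between brain regions (e.g. streamline counts from tractography).  The
linear noise-diffusion model couples regions through ``A = -I + c W``:
each node relaxes towards zero with unit rate while receiving input from
its neighbours scaled by the global coupling ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StructuralNetwork",
    "CouplingSpec",
    "NoiseSpec",
    "TimeSeriesData",
    "UnstableRegimeError",
    "SingularCovarianceError",
]

#: Condition-number threshold above which a matrix is treated as singular.
CONDITION_LIMIT = 1e12

#: Relative margin used for the strict stability inequality c < c_critic.
STABILITY_MARGIN = 1e-9


class UnstableRegimeError(ValueError):
    """Raised when the requested coupling puts the linear model past its
    stability boundary (c >= c_critic)."""


class SingularCovarianceError(ValueError):
    """Raised when a covariance matrix cannot be inverted reliably."""


def _as_square(weights) -> np.ndarray:
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weights must be a square matrix, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite (no NaN/inf entries)")
    return W


@dataclass(frozen=True)
class StructuralNetwork:
    """Weighted structural connectivity matrix with region metadata.

    Parameters
    ----------
    weights
        Square ``(n, n)`` matrix of connection weights.  The diagonal must
        be zero: self-connections are fixed at -1 by the model and are not
        part of the structure.
    labels
        Optional region names, length ``n``.
    hemisphere
        Optional per-region hemisphere tags from ``{"left", "right",
        "none"}``.
    """

    weights: np.ndarray
    labels: tuple[str, ...] | None = None
    hemisphere: tuple[str, ...] | None = None

    def __post_init__(self):
        W = _as_square(self.weights)
        if np.any(np.diag(W) != 0.0):
            raise ValueError(
                "structural matrix must have a zero diagonal; "
                "use StructuralNetwork.from_sc to strip it"
            )
        object.__setattr__(self, "weights", W)
        n = W.shape[0]
        for name in ("labels", "hemisphere"):
            val = getattr(self, name)
            if val is not None:
                val = tuple(val)
                if len(val) != n:
                    raise ValueError(f"{name} must have length {n}, got {len(val)}")
                object.__setattr__(self, name, val)
        if self.hemisphere is not None:
            bad = set(self.hemisphere) - {"left", "right", "none"}
            if bad:
                raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")

    @classmethod
    def from_sc(cls, sc, labels=None, hemisphere=None) -> "StructuralNetwork":
        """Build a network from a raw SC matrix, removing the diagonal."""
        W = _as_square(sc).copy()
        np.fill_diagonal(W, 0.0)
        return cls(W, labels=labels, hemisphere=hemisphere)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.weights, self.weights.T))

    def symmetrized(self) -> "StructuralNetwork":
        W = 0.5 * (self.weights + self.weights.T)
        return StructuralNetwork(W, labels=self.labels, hemisphere=self.hemisphere)


@dataclass(frozen=True)
class CouplingSpec:
    """Stability information for a structural network.

    ``c_critic = 1 / max_i lambda_i`` where ``lambda_i`` are the
    eigenvalues of W (real parts for asymmetric W).  The equilibrium of
    ``dx = (-I + cW) x dt + noise`` is stable iff ``c < c_critic``.
    """

    c_critic: float
    eigenvalues_W: np.ndarray
    c: float = 0.0

    def is_stable(self, c: float) -> bool:
        return c < self.c_critic * (1.0 - STABILITY_MARGIN)


@dataclass(frozen=True)
class NoiseSpec:
    """White-noise amplitude: uniform scalar sigma or per-node vector.

    ``Sigma`` is the noise covariance ``sigma sigma^t`` (diagonal here:
    independent noise sources per node).
    """

    sigma: float | np.ndarray = 1.0

    def __post_init__(self):
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim == 0:
            if s <= 0:
                raise ValueError("sigma must be strictly positive")
            object.__setattr__(self, "sigma", float(s))
        elif s.ndim == 1:
            if np.any(s <= 0):
                raise ValueError("all entries of sigma must be strictly positive")
            object.__setattr__(self, "sigma", s)
        else:
            raise ValueError("sigma must be a scalar or a 1-D vector")

    @property
    def is_uniform(self) -> bool:
        return np.ndim(self.sigma) == 0

    def sigma_vector(self, n: int) -> np.ndarray:
        if self.is_uniform:
            return np.full(n, float(self.sigma))
        s = np.asarray(self.sigma)
        if s.shape[0] != n:
            raise ValueError(f"sigma vector has length {s.shape[0]}, expected {n}")
        return s

    def Sigma(self, n: int) -> np.ndarray:
        """Noise covariance matrix (diagonal)."""
        return np.diag(self.sigma_vector(n) ** 2)


@dataclass(frozen=True)
class TimeSeriesData:
    """Multivariate signal sampled at a fixed interval.

    ``values`` is ``(T, n)``: time along the first axis, one column per
    region.  ``dt`` is the sampling interval in the declared time unit
    (seconds for BOLD-like series, model units for OU runs).
    """

    values: np.ndarray
    dt: float
    labels: tuple[str, ...] | None = None
    time_unit: str = "s"

    def __post_init__(self):
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("values must be a (T, n) matrix with T >= 2")
        if not np.all(np.isfinite(X)):
            raise ValueError("time series contains NaN or infinite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", X)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != X.shape[1]:
                raise ValueError("labels length must match number of columns")
            object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def covariance(self, ddof: int = 0) -> np.ndarray:
        """Sample covariance across time (biased 1/T by default)."""
        X = self.values - self.values.mean(axis=0)
        return (X.T @ X) / (self.n_samples - ddof)

    def correlation(self) -> np.ndarray:
        return np.corrcoef(self.values, rowvar=False)
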