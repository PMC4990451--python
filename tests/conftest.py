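"""Shared fixtures: small synthetic networks and covariances."""

import numpy as np
import pytest

from conndiff import NoiseSpec, StructuralNetwork, analytic_covariance, critical_coupling


def random_symmetric_net(n: int, seed: int, density: float = 0.6) -> StructuralNetwork:
    """Random nonnegative symmetric zero-diagonal network (always has a
    positive leading eigenvalue when any edge exists)."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, k=1)
    W = W + W.T
    if not np.any(W):  # ensure at least one edge
        W[0, 1] = W[1, 0] = 1.0
    return StructuralNetwork(W)


@pytest.fixture
def exchange_net() -> StructuralNetwork:
    """Two mutually coupled nodes: eigenvalues of W are +-1, c_critic = 1."""
    return StructuralNetwork(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def exchange_cov() -> np.ndarray:
    """Stationary covariance of the exchange net at c=0.5, sigma=1
    (brute-force inversion of A = [[-1, 0.5], [0.5, -1]])."""
    return np.array([[2.0 / 3.0, 1.0 / 3.0], [1.0 / 3.0, 2.0 / 3.0]])


@pytest.fixture
def small_net() -> StructuralNetwork:
    return random_symmetric_net(8, seed=42)


def stable_coupling(net: StructuralNetwork, frac: float = 0.8) -> float:
    return frac * critical_coupling(net).c_critic


def forward_cov(net: StructuralNetwork, frac: float = 0.8, sigma: float = 1.0):
    c = stable_coupling(net, frac)
    return analytic_covariance(net, c, NoiseSpec(sigma)), c
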