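"""Sensitivity of the stationary covariance to a structural edge edit.

A symmetric perturbation of a single edge, ``W'_{ij} = W_{ij} + eps``
(and its mirror), shifts the drift matrix by ``dA = c eps (e_i e_j^T +
e_j e_i^T)``.  To first order in eps the covariance responds as

    C' ~ C + (2/sigma^2) C dA C,

the resolvent expansion of ``-(sigma^2/2)(A + dA)^{-1}``.  The exact
response is obtained by recomputing the forward operator on the edited
network; the difference between the two is O(eps^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import analytic_covariance
from .network import NoiseSpec, StructuralNetwork

__all__ = ["EdgePerturbation", "perturb_edge_covariance", "perturbed_network"]


@dataclass(frozen=True)
class EdgePerturbation:
    """A symmetric single-edge amplitude change of magnitude eps."""

    i: int
    j: int
    eps: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("edge perturbation requires two distinct nodes (i != j)")


def perturbed_network(net: StructuralNetwork, pert: EdgePerturbation) -> StructuralNetwork:
    """The network with entries (i, j) and (j, i) shifted by eps."""
    W = net.weights.copy()
    W[pert.i, pert.j] += pert.eps
    W[pert.j, pert.i] += pert.eps
    return StructuralNetwork(W, labels=net.labels, hemisphere=net.hemisphere)


def perturb_edge_covariance(
    net: StructuralNetwork,
    c: float,
    noise: NoiseSpec | float = 1.0,
    pert: EdgePerturbation | None = None,
    mode: str = "exact",
) -> np.ndarray:
    """Covariance of the edge-perturbed network.

    mode="exact" recomputes the forward operator on W'; the perturbed
    system must itself be stable.  mode="first_order" applies the linear
    response ``C + (2/sigma^2) C dA C`` without re-inverting.
    """
    if pert is None:
        raise ValueError("an EdgePerturbation must be provided")
    if isinstance(noise, (int, float)):
        noise = NoiseSpec(noise)
    n = net.n_regions
    if not (0 <= pert.i < n and 0 <= pert.j < n):
        raise ValueError("perturbation indices out of range")
    if mode == "exact":
        return analytic_covariance(perturbed_network(net, pert), c, noise)
    if mode == "first_order":
        if not noise.is_uniform:
            raise ValueError("first-order response implemented for uniform sigma")
        C = analytic_covariance(net, c, noise)
        dA = np.zeros((n, n))
        dA[pert.i, pert.j] = c * pert.eps
        dA[pert.j, pert.i] = c * pert.eps
        sigma2 = float(noise.sigma) ** 2
        return C + (2.0 / sigma2) * (C @ dA @ C)
    raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'first_order'")
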