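"""Network time-series simulators used to validate the analytic operators.

Two generators are provided:

* the linear Ornstein-Uhlenbeck (OU) process ``dx = (-I + cW) x dt +
  sigma dxi`` — the model whose stationary covariance the forward
  operator computes in closed form;
* the reduced Wong-Wang mean-field model, a nonlinear one-equation-per-
  region description of average synaptic gating with a sigmoidal
  firing-rate transfer function, used to check that structure can still
  be recovered from covariances of nonlinear dynamics.

Both use stochastic Euler (Euler-Maruyama) integration with noise
increments scaled by sqrt(dt), and a mandatory seed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forward import coupling_matrix, critical_coupling
from .network import NoiseSpec, StructuralNetwork, TimeSeriesData, UnstableRegimeError

__all__ = [
    "simulate_ou",
    "WongWangParams",
    "wong_wang_transfer",
    "wong_wang_fixed_point_residual",
    "simulate_wong_wang",
]

_NOISE_CHUNK = 20_000  # Gaussian increments drawn in blocks to amortize RNG cost


def simulate_ou(
    net: StructuralNetwork,
    c: float,
    noise: NoiseSpec | float = 1.0,
    duration: float = 1000.0,
    dt: float = 0.05,
    burn_in: float = 20.0,
    seed: int | None = None,
) -> TimeSeriesData:
    """Euler-Maruyama trajectory of the linear noise-diffusion model.

    Time is in model units (the single-node relaxation time is 1).  The
    burn-in segment is discarded so the retained samples come from the
    stationary state.  ``dt`` must be well below the relaxation time;
    steps of 0.5 or more are rejected as unstable for the explicit
    integrator.
    """
    if isinstance(noise, (int, float)):
        noise = NoiseSpec(noise)
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if dt <= 0 or dt >= 0.5:
        raise ValueError("dt must lie in (0, 0.5) model-time units")
    if duration <= 0:
        raise ValueError("duration must be positive")
    spec = critical_coupling(net) if np.any(net.weights) else None
    if spec is not None and not spec.is_stable(c):
        raise UnstableRegimeError(
            f"unstable regime: c={c:g} >= c_critic={spec.c_critic:g}"
        )
    n = net.n_regions
    A = coupling_matrix(net, c)
    M = np.eye(n) + dt * A  # one explicit Euler step
    sig = noise.sigma_vector(n) * np.sqrt(dt)

    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    out = np.empty((n_keep, n))
    total = n_burn + n_keep
    done = 0
    while done < total:
        block = min(_NOISE_CHUNK, total - done)
        xi = rng.standard_normal((block, n))
        for k in range(block):
            x = M @ x + sig * xi[k]
            idx = done + k - n_burn
            if idx >= 0:
                out[idx] = x
        done += block
    return TimeSeriesData(out, dt=dt, labels=net.labels, time_unit="model")


@dataclass(frozen=True)
class WongWangParams:
    """Parameters of the reduced Wong-Wang mean-field model.

    Units: ``a`` in 1/nC, ``b`` in Hz, ``d`` in s, ``tau_S`` in ms,
    ``J_N`` and ``I_0`` in nA; ``gamma`` converts firing rate (Hz) to
    gating-variable drive per millisecond.  ``sigma`` is the noise
    amplitude on the gating variable; ``c`` the global coupling.
    """

    w: float = 0.9
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641 / 1000.0
    tau_S: float = 100.0
    J_N: float = 0.2609
    I_0: float = 0.3
    sigma: float = 0.00005
    c: float = 0.0

    def with_(self, **kw) -> "WongWangParams":
        return replace(self, **kw)


def wong_wang_transfer(x, params: WongWangParams = WongWangParams()):
    """Population firing rate ``H(x) = (ax - b) / (1 - exp(-d(ax - b)))`` in Hz.

    The singularity at ``ax = b`` is removable; there ``H = 1/d``.  The
    function is strictly positive and asymptotically linear for large
    input currents.
    """
    x = np.asarray(x, dtype=float)
    y = params.a * x - params.b
    dy = params.d * y
    with np.errstate(over="ignore", invalid="ignore"):
        H = np.where(
            np.abs(dy) < 1e-8,
            1.0 / params.d + y / 2.0,  # series at the removable singularity
            y / -np.expm1(-dy),
        )
    if H.ndim == 0:
        return float(H)
    return H


def _ww_drift(S: np.ndarray, W: np.ndarray, p: WongWangParams) -> np.ndarray:
    x = p.w * p.J_N * S + p.c * p.J_N * (W @ S) + p.I_0
    return -S / p.tau_S + (1.0 - S) * p.gamma * wong_wang_transfer(x, p)


def wong_wang_fixed_point_residual(
    S: np.ndarray, net: StructuralNetwork, params: WongWangParams
) -> np.ndarray:
    """Residual ``S/tau_S - (1-S) gamma H(x)`` of the noise-free balance."""
    return -_ww_drift(np.asarray(S, dtype=float), net.weights, params)


def simulate_wong_wang(
    net: StructuralNetwork,
    params: WongWangParams = WongWangParams(),
    duration_ms: float = 60_000.0,
    dt_ms: float = 0.1,
    store_every: int = 10,
    burn_in_ms: float = 0.0,
    seed: int | None = None,
) -> TimeSeriesData:
    """Stochastic Euler integration of the Wong-Wang gating variables.

    The default 0.1 ms step with decimation 10 stores 1 ms samples, so a
    20-minute run yields 1.2 million points.  Gating variables are
    integrated exactly as written (no clipping to [0, 1]); excursions
    outside the unit interval, which occur only through noise, are left
    in the trajectory.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if dt_ms <= 0 or duration_ms <= 0:
        raise ValueError("dt_ms and duration_ms must be positive")
    if store_every < 1:
        raise ValueError("store_every must be >= 1")
    n = net.n_regions
    W = net.weights
    p = params
    sqdt = np.sqrt(dt_ms)
    n_burn = int(round(burn_in_ms / dt_ms))
    n_steps = int(round(duration_ms / dt_ms))
    n_store = n_steps // store_every
    if n_store < 2:
        raise ValueError("duration too short for the requested decimation")
    rng = np.random.default_rng(seed)
    S = np.full(n, 0.1)
    out = np.empty((n_store, n))
    stored = 0
    total = n_burn + n_steps
    done = 0
    while done < total:
        block = min(_NOISE_CHUNK, total - done)
        nu = rng.standard_normal((block, n))
        for k in range(block):
            S = S + dt_ms * _ww_drift(S, W, p) + p.sigma * sqdt * nu[k]
            step = done + k - n_burn
            if step >= 0 and (step + 1) % store_every == 0 and stored < n_store:
                out[stored] = S
                stored += 1
        done += block
    return TimeSeriesData(
        out[:stored], dt=dt_ms * store_every, labels=net.labels, time_unit="ms"
    )
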