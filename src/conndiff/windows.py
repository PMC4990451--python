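"""Sliding-window engine for time-varying connectivity.

Windows of a fixed length (in seconds) are advanced by a fixed step
across the series; each window yields a covariance (within-window mean
removed, 1/w normalization) to which the analytic operators can be
applied — windowed inverse structure (aSC_w), or a windowed coupling
sweep that tracks how the best-fitting global coupling drifts through a
scan session.  Incomplete windows at the end of the series are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inverse import DEFAULT_C, DEFAULT_SIGMA, InverseResult, analytic_sc
from .network import SingularCovarianceError, StructuralNetwork, TimeSeriesData
from .sweep import SweepResult, sweep_coupling

__all__ = [
    "WindowSpec",
    "make_windows",
    "window_covariances",
    "windowed_inverse_sc",
    "windowed_sweep",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in both seconds and samples."""

    length_s: float
    step_s: float
    length_samples: int
    step_samples: int
    starts: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def make_windows(ts: TimeSeriesData, length_s: float, step_s: float) -> WindowSpec:
    """Window layout: lengths floor to samples, windows are half-open
    ``[start, start + length)``, and only fully contained windows count."""
    length_samples = int(np.floor(length_s / ts.dt))
    step_samples = max(1, int(np.floor(step_s / ts.dt)))
    if length_samples < 2:
        raise ValueError("window shorter than two samples")
    T = ts.n_samples
    if length_samples > T:
        raise ValueError(
            f"window of {length_samples} samples exceeds series length {T}"
        )
    n_win = (T - length_samples) // step_samples + 1
    starts = tuple(range(0, n_win * step_samples, step_samples))
    return WindowSpec(
        length_s=length_s,
        step_s=step_s,
        length_samples=length_samples,
        step_samples=step_samples,
        starts=starts,
    )


def window_covariances(ts: TimeSeriesData, spec: WindowSpec) -> np.ndarray:
    """Per-window covariance stack, shape (n_windows, n, n).

    Each window subtracts its own mean and normalizes by the window
    length w (biased form)."""
    X = ts.values
    w = spec.length_samples
    out = np.empty((spec.n_windows, ts.n_regions, ts.n_regions))
    for k, s in enumerate(spec.starts):
        seg = X[s : s + w]
        seg = seg - seg.mean(axis=0)
        out[k] = (seg.T @ seg) / w
    return out


def windowed_inverse_sc(
    ts: TimeSeriesData,
    spec: WindowSpec,
    c: float = DEFAULT_C,
    sigma: float = DEFAULT_SIGMA,
    clip_negative: bool = False,
) -> tuple[list[InverseResult], np.ndarray]:
    """Inverse operation per window plus the per-link SD across windows.

    Windows must be longer than the number of regions so the window
    covariance is invertible.  A small per-link standard deviation marks
    a stable contribution of that anatomical link to function; large SD
    marks a fluctuating one.
    """
    if spec.length_samples <= ts.n_regions:
        raise ValueError(
            "window length must exceed the number of regions for an "
            "invertible window covariance"
        )
    covs = window_covariances(ts, spec)
    results: list[InverseResult] = []
    for k, C in enumerate(covs):
        try:
            results.append(analytic_sc(C, c=c, noise=sigma, clip_negative=clip_negative))
        except SingularCovarianceError as err:
            raise SingularCovarianceError(
                f"window {k} (start sample {spec.starts[k]}): {err}"
            ) from err
    stack = np.stack([r.W_hat for r in results])
    sd = stack.std(axis=0)
    return results, sd


def windowed_sweep(
    ts: TimeSeriesData,
    net: StructuralNetwork,
    spec: WindowSpec,
    grid_size: int = 200,
    keep_diagonal: bool = True,
) -> list[SweepResult]:
    """Coupling sweep against each window's correlation matrix.

    The critical coupling is constant (structure is fixed); the
    per-window optimum tracks apparent non-stationarity of the coupling.
    """
    X = ts.values
    w = spec.length_samples
    results = []
    for k, s in enumerate(spec.starts):
        seg = X[s : s + w]
        sds = seg.std(axis=0)
        if np.any(sds == 0):
            raise ValueError(
                f"window {k} has zero-variance regions; correlation undefined"
            )
        fc = np.corrcoef(seg, rowvar=False)
        results.append(sweep_coupling(net, fc, grid_size, keep_diagonal))
    return results
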