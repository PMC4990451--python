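"""Connectome-like synthetic data: structural matrices, cohorts, BOLD-like series.

The generator emulates the gross features of a tractography-derived
cortical connectome on a two-hemisphere parcellation: heavy-tailed
(log-normal) weights, modular intra-hemispheric blocks, sparse
inter-hemispheric links, and strong homotopic connections between
mirror-symmetric regions — which sit on the antidiagonal when regions
are ordered left hemisphere first and right hemisphere mirrored.
Cohorts add per-subject multiplicative weight variability; BOLD-like
series are Ornstein-Uhlenbeck trajectories decimated to a repetition
time (TR) with optional additive measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import NoiseSpec, StructuralNetwork, TimeSeriesData
from .simulate import simulate_ou

__all__ = ["SynthConfig", "synth_sc", "synth_cohort", "synth_bold"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic connectome generator.

    Densities are connection probabilities; weights are log-normal
    (``exp(N(log_mu, log_sd^2))``) to mimic the heavy tail of streamline
    counts, scaled per connection class.  ``homotopic_strength`` sets the
    antidiagonal inter-hemispheric weight scale (0 removes them).
    """

    n_regions: int = 66
    n_modules: int = 3  # per hemisphere
    intra_module_density: float = 0.7
    between_module_density: float = 0.15
    inter_hemispheric_density: float = 0.05
    intra_weight_scale: float = 1.0
    inter_weight_scale: float = 0.3
    homotopic_strength: float = 0.8
    log_mu: float = 0.0
    log_sd: float = 0.6
    subject_variability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_regions % 2 != 0:
            raise ValueError(
                "n_regions must be even: each region needs a homotopic "
                "partner in the opposite hemisphere"
            )
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


def _hemisphere_tags(n: int) -> tuple[str, ...]:
    h = n // 2
    return ("left",) * h + ("right",) * h


def synth_sc(config: SynthConfig = SynthConfig()) -> StructuralNetwork:
    """Draw a symmetric, nonnegative, zero-diagonal synthetic connectome.

    Regions 0..n/2-1 are the left hemisphere; the right hemisphere is
    mirrored so the homotopic partner of region k is region n-1-k.
    """
    n = config.n_regions
    h = n // 2
    rng = np.random.default_rng(config.seed)
    module = np.floor(np.arange(h) * config.n_modules / h).astype(int)

    def lognorm(size=None):
        return np.exp(rng.normal(config.log_mu, config.log_sd, size=size))

    W = np.zeros((n, n))
    # intra-hemispheric blocks (left built, right mirrored with fresh draws)
    for hemi_offset, mirror in ((0, False), (h, True)):
        for a in range(h):
            for b in range(a + 1, h):
                dens = (
                    config.intra_module_density
                    if module[a] == module[b]
                    else config.between_module_density
                )
                if rng.random() < dens:
                    wgt = config.intra_weight_scale * lognorm()
                    if mirror:
                        i, j = n - 1 - a, n - 1 - b
                    else:
                        i, j = a, b
                    W[i, j] = W[j, i] = wgt
    # sparse non-homotopic inter-hemispheric links
    for a in range(h):
        for b in range(h, n):
            if b == n - 1 - a:
                continue
            if rng.random() < config.inter_hemispheric_density:
                wgt = config.inter_weight_scale * lognorm()
                W[a, b] = W[b, a] = wgt
    # strong homotopic antidiagonal links
    if config.homotopic_strength > 0:
        for a in range(h):
            wgt = config.homotopic_strength * lognorm()
            W[a, n - 1 - a] = W[n - 1 - a, a] = wgt
    labels = tuple(
        f"{'L' if k < h else 'R'}{(k if k < h else n - 1 - k):02d}" for k in range(n)
    )
    return StructuralNetwork(W, labels=labels, hemisphere=_hemisphere_tags(n))


def synth_cohort(
    base: StructuralNetwork,
    n_subjects: int,
    variability: float = 0.3,
    seed: int = 0,
) -> list[StructuralNetwork]:
    """Per-subject connectomes by multiplicative log-normal weight jitter.

    Each existing edge weight is multiplied by ``exp(N(0, variability^2))``
    (independently per subject and edge, symmetrically applied), so
    variability = 0 reproduces the base exactly and larger values lower
    the pairwise between-subject correlation.
    """
    if variability < 0:
        raise ValueError("variability must be nonnegative")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n = base.n_regions
    upper = np.triu_indices(n, k=1)
    subjects = []
    for _ in range(n_subjects):
        W = base.weights.copy()
        jitter = np.exp(rng.normal(0.0, variability, size=len(upper[0])))
        W[upper] *= jitter
        W.T[upper] = W[upper]
        subjects.append(
            StructuralNetwork(W, labels=base.labels, hemisphere=base.hemisphere)
        )
    return subjects


def synth_bold(
    net: StructuralNetwork,
    c: float,
    noise: NoiseSpec | float = 1.0,
    tr_s: float = 1.94,
    duration_s: float = 1200.0,
    measurement_noise: float = 0.0,
    seed: int = 0,
    dt_target: float = 0.05,
) -> TimeSeriesData:
    """BOLD-like surrogate series: OU dynamics sampled at the TR.

    One model-time unit is taken as one second (node relaxation on the
    hemodynamic scale).  The trajectory is integrated at a fine step,
    decimated to the repetition time, and optionally degraded with
    additive white measurement noise.
    """
    if tr_s <= 0 or duration_s <= tr_s:
        raise ValueError("need tr_s > 0 and duration_s > tr_s")
    if measurement_noise < 0:
        raise ValueError("measurement_noise must be nonnegative")
    decim = max(1, int(round(tr_s / dt_target)))
    dt = tr_s / decim
    ts = simulate_ou(
        net, c, noise, duration=duration_s, dt=dt, burn_in=20.0, seed=seed
    )
    X = ts.values[decim - 1 :: decim]
    if measurement_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB01D]))
        X = X + measurement_noise * rng.standard_normal(X.shape)
    return TimeSeriesData(X, dt=tr_s, labels=net.labels, time_unit="s")
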