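"""Matrix-comparison statistics.

Connectivity matrices are symmetric, so comparisons use the lower
triangle with the diagonal excluded unless a partition says otherwise.
Confidence intervals come from a percentile bootstrap over masked
entry pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = ["TrianglePartition", "matrix_correlation", "bootstrap_ci"]

_KINDS = ("lower_offdiag", "with_diagonal", "intra_hemispheric", "inter_hemispheric")


@dataclass(frozen=True)
class TrianglePartition:
    """Boolean mask selecting which matrix entries enter a comparison."""

    mask: np.ndarray
    kind: str

    @classmethod
    def lower_offdiag(cls, n: int) -> "TrianglePartition":
        """Lower triangle, diagonal excluded (the default for symmetric matrices)."""
        return cls(np.tril(np.ones((n, n), dtype=bool), k=-1), "lower_offdiag")

    @classmethod
    def with_diagonal(cls, n: int) -> "TrianglePartition":
        """Lower triangle including the diagonal (used during coupling sweeps,
        where keeping variances helps scale covariances against each other)."""
        return cls(np.tril(np.ones((n, n), dtype=bool), k=0), "with_diagonal")

    @classmethod
    def hemispheric(cls, hemisphere, kind: str) -> "TrianglePartition":
        """Intra- or inter-hemispheric split of the lower off-diagonal triangle.

        Regions tagged "none" are excluded from both partitions.
        """
        if kind not in ("intra_hemispheric", "inter_hemispheric"):
            raise ValueError(f"kind must be intra/inter_hemispheric, got {kind!r}")
        tags = np.asarray(hemisphere, dtype=object)
        n = tags.shape[0]
        lower = np.tril(np.ones((n, n), dtype=bool), k=-1)
        tagged = (tags != "none")[:, None] & (tags != "none")[None, :]
        same = tags[:, None] == tags[None, :]
        if kind == "intra_hemispheric":
            mask = lower & tagged & same
        else:
            mask = lower & tagged & ~same
        return cls(mask, kind)


def _masked_pairs(m1, m2, part: TrianglePartition):
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError(f"shape mismatch: {m1.shape} vs {m2.shape}")
    if part.mask.shape != m1.shape:
        raise ValueError("partition mask shape does not match matrices")
    x = m1[part.mask]
    y = m2[part.mask]
    if x.size < 3:
        raise ValueError("partition selects fewer than 3 entries")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("masked entries contain NaN")
    return x, y


def matrix_correlation(m1, m2, part: TrianglePartition | None = None) -> float:
    """Pearson correlation of the masked entries of two matrices."""
    if part is None:
        part = TrianglePartition.lower_offdiag(np.asarray(m1).shape[0])
    x, y = _masked_pairs(m1, m2, part)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in masked entries; correlation undefined")
    return float(sp_stats.pearsonr(x, y).statistic)


def bootstrap_ci(
    m1,
    m2,
    part: TrianglePartition | None = None,
    n_resamples: int = 10_000,
    alpha: float = 0.01,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the masked-entry Pearson correlation.

    Entry pairs are resampled with replacement; the interval is the
    (alpha/2, 1 - alpha/2) percentile range of the resampled correlations.
    """
    if part is None:
        part = TrianglePartition.lower_offdiag(np.asarray(m1).shape[0])
    x, y = _masked_pairs(m1, m2, part)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in masked entries; correlation undefined")
    rng = np.random.default_rng(seed)
    m = x.size
    rs = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, m, size=m)
        xb, yb = x[idx], y[idx]
        sx, sy = xb.std(), yb.std()
        if sx == 0 or sy == 0:
            rs[b] = 1.0 if np.array_equal(xb, yb) else 0.0
            continue
        rs[b] = ((xb - xb.mean()) * (yb - yb.mean())).mean() / (sx * sy)
    lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
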