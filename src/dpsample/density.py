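"""Smoothed-data-histogram density estimates on a fixed kernel grid.

A variable's PDF is evaluated at 200 equally spaced kernel centers spanning
the variable's range.  Each observation votes for its ``s`` nearest centers
with linearly decreasing rank weights (s, s-1, ..., 1); the accumulated
weights are normalized so the Riemann sum of the density equals one.  The
grid is always built from the *full* data's range so that a subsample (a
subset, hence within range) and the full data are compared on identical
support.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: number of kernel centers spanning the variable's range
DEFAULT_N_KERNELS = 200
#: number of nearest kernels each observation votes for (10% of the grid)
DEFAULT_SMOOTHING = 20


@dataclasses.dataclass(frozen=True)
class Grid:
    """Equally spaced kernel centers over a reference variable's range.

    A degenerate (constant) reference collapses to a single center carrying
    unit mass; ``bin_width`` is set to 1 there so normalization still holds.
    """

    centers: np.ndarray
    bin_width: float

    @property
    def degenerate(self) -> bool:
        return self.centers.size == 1

    @property
    def n_kernels(self) -> int:
        return self.centers.size


@dataclasses.dataclass(frozen=True)
class DensityEstimate:
    grid: Grid
    density: np.ndarray  # non-negative, Riemann sum density*bin_width == 1

    @property
    def mass(self) -> np.ndarray:
        """Per-kernel probability mass (density times bin width)."""
        return self.density * self.grid.bin_width


def make_grid(reference_values, n_kernels: int = DEFAULT_N_KERNELS) -> Grid:
    """Build ``n_kernels`` equally spaced centers spanning [min, max].

    A constant reference yields the degenerate single-center grid.
    """
    values = np.asarray(reference_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("reference values must be non-empty")
    if n_kernels < 2:
        raise ValueError("n_kernels must be >= 2")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return Grid(centers=np.array([lo]), bin_width=1.0)
    centers = np.linspace(lo, hi, n_kernels)
    return Grid(centers=centers, bin_width=(hi - lo) / (n_kernels - 1))


def estimate_pdf(values, grid: Grid, smoothing_s: int = DEFAULT_SMOOTHING) -> DensityEstimate:
    """Smoothed data histogram of ``values`` on ``grid``.

    Each point contributes weight ``s - r + 1`` to its r-th nearest center,
    r = 1..s, ties in rank broken toward the lower-index center; weights are
    normalized to a unit Riemann sum.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if smoothing_s < 1:
        raise ValueError("smoothing_s must be positive")
    if grid.degenerate:
        return DensityEstimate(grid=grid, density=np.array([1.0]))

    centers = grid.centers
    k = centers.size
    s = min(smoothing_s, k)
    weights = np.zeros(k)
    # On a uniform grid the s nearest centers form a contiguous window, so
    # ranking distances inside a (s+1)-wide window around each point suffices.
    h = grid.bin_width
    j0 = np.clip(np.rint((x - centers[0]) / h).astype(int), 0, k - 1)
    # window of +-s around the nearest center covers the s nearest even at
    # the grid edges; out-of-range candidates get infinite distance
    offsets = np.arange(-s, s + 1)
    cand = j0[:, None] + offsets[None, :]
    valid = (cand >= 0) & (cand < k)
    cand_c = np.where(valid, cand, 0)
    dist = np.abs(x[:, None] - centers[cand_c])
    dist[~valid] = np.inf
    # stable sort -> equidistant candidates resolved toward the lower index
    # (candidate columns are ordered by grid index)
    order = np.argsort(dist, axis=1, kind="stable")[:, :s]
    chosen = np.take_along_axis(cand_c, order, axis=1)
    rank_w = (s - np.arange(s)).astype(float)  # s, s-1, ..., 1
    np.add.at(weights, chosen.ravel(), np.broadcast_to(rank_w, chosen.shape).ravel())
    total = weights.sum() * grid.bin_width
    return DensityEstimate(grid=grid, density=weights / total)
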