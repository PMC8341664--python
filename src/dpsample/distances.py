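"""Two-sample distribution distances used as the sample-selection criterion.

Six statistics operate on the raw values through their empirical CDFs
(Anderson-Darling ``ad``, Kuiper ``kuiper``, Cramér-von Mises ``cvm``,
1-Wasserstein ``wass``, the variance-weighted ECDF distance ``dts`` and
Kolmogorov-Smirnov ``ks``); three compare kernel-density estimates on the
full data's grid (symmetrized Kullback-Leibler ``kld``, Euclidean ``euc``
and the absolute mean relative density difference ``amrdd``).  All nine are
dissimilarities: smaller means the sample's distribution is closer to the
full data's.  Raw statistics are returned, not p-values — the selection
rule is an argmin, so null calibration would add nothing.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats

from .core_io import ECDF_METRICS, PDF_METRICS, normalize_metric_id
from .density import DensityEstimate, Grid, estimate_pdf, make_grid

#: floor applied to kernel masses before the symmetrized KL divergence
KLD_EPS = 1e-12


def _as_vec(a, name: str) -> np.ndarray:
    v = np.asarray(a, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return v


# --------------------------------------------------------------------------
# ECDF-based statistics
# --------------------------------------------------------------------------

def ks_stat(x, y) -> float:
    """Kolmogorov-Smirnov distance: sup |F1 - F2| over the pooled support."""
    x = _as_vec(x, "x")
    y = _as_vec(y, "y")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


def kuiper_stat(x, y) -> float:
    """Kuiper statistic V = sup(F1 - F2) + sup(F2 - F1), in [0, 2]."""
    x = _as_vec(x, "x")
    y = _as_vec(y, "y")
    z = np.concatenate([x, y])
    z.sort()
    d = np.searchsorted(np.sort(x), z, side="right") / x.size \
        - np.searchsorted(np.sort(y), z, side="right") / y.size
    return float(max(d.max(), 0.0) + max(-d.min(), 0.0))


def cvm_stat(x, y) -> float:
    """Two-sample Cramér-von Mises statistic in its rank form.

    T = U / (n m N) - (4 m n - 1) / (6 N) with
    U = n * sum_i (r_i - i)^2 + m * sum_j (s_j - j)^2 over midranks of the
    pooled sample (ties get average ranks).
    """
    x = _as_vec(x, "x")
    y = _as_vec(y, "y")
    n, m = x.size, y.size
    N = n + m
    r = stats.rankdata(np.concatenate([x, y]), method="average")
    rx = np.sort(r[:n])
    ry = np.sort(r[n:])
    u = n * np.sum((rx - np.arange(1, n + 1)) ** 2) \
        + m * np.sum((ry - np.arange(1, m + 1)) ** 2)
    return float(u / (n * m * N) - (4.0 * m * n - 1.0) / (6.0 * N))


def ad_stat(x, y) -> float:
    """Two-sample Anderson-Darling statistic (raw, unstandardized).

    A2 = (1 / (n m)) * sum_{k=1}^{N-1} (M_k N - n k)^2 / (k (N - k)) where
    M_k counts x-observations among the k smallest pooled values.  Tied
    pooled values are handled as one block weighted by its multiplicity,
    which reduces to the plain k-sum on tie-free data.
    """
    x = _as_vec(x, "x")
    y = _as_vec(y, "y")
    n, m = x.size, y.size
    N = n + m
    z, t = np.unique(np.concatenate([x, y]), return_counts=True)
    if z.size == 1:
        return 0.0
    K = np.cumsum(t)
    M = np.searchsorted(np.sort(x), z, side="right")
    keep = K < N  # the final block has N - K = 0 and zero numerator weight
    num = (M[keep] * float(N) - n * K[keep].astype(float)) ** 2
    s = np.sum(t[keep] * num / (K[keep] * (N - K[keep])))
    return float(s / (n * m))


def wasserstein_stat(x, y) -> float:
    """1-Wasserstein distance: integral of |F1 - F2| over the real line."""
    x = _as_vec(x, "x")
    y = _as_vec(y, "y")
    return float(stats.wasserstein_distance(x, y))


def dts_stat(x, y) -> float:
    """Variance-weighted ECDF distance.

    Integral of |F1 - F2| / sqrt(Fp (1 - Fp)) dt with Fp the pooled ECDF;
    intervals where Fp is 0 or 1 are excluded (the weight is undefined
    there and the integrand vanishes at Fp = 1 anyway).  The weighting
    emphasizes discrepancies in the distribution tails.
    """
    x = _as_vec(x, "x")
    y = _as_vec(y, "y")
    n, m = x.size, y.size
    z = np.unique(np.concatenate([x, y]))
    if z.size == 1:
        return 0.0
    f1 = np.searchsorted(np.sort(x), z, side="right") / n
    f2 = np.searchsorted(np.sort(y), z, side="right") / m
    fp = np.searchsorted(np.sort(np.concatenate([x, y])), z, side="right") / (n + m)
    widths = np.diff(z)
    num = np.abs(f1 - f2)[:-1]
    w = fp[:-1]
    mask = (w > 0.0) & (w < 1.0)
    return float(np.sum(num[mask] / np.sqrt(w[mask] * (1.0 - w[mask])) * widths[mask]))


# --------------------------------------------------------------------------
# kernel-density based distances
# --------------------------------------------------------------------------

def _check_same_grid(p: DensityEstimate, q: DensityEstimate) -> None:
    if p.grid is not q.grid and not (
        p.grid.bin_width == q.grid.bin_width
        and np.array_equal(p.grid.centers, q.grid.centers)
    ):
        raise ValueError("density estimates must share the same kernel grid")


def euclidean_pdf_dist(p: DensityEstimate, q: DensityEstimate) -> float:
    """l2 norm of the density difference over the kernel centers."""
    _check_same_grid(p, q)
    return float(np.linalg.norm(p.density - q.density))


def kld_sym_dist(p: DensityEstimate, q: DensityEstimate) -> float:
    """Symmetrized Kullback-Leibler divergence KL(p||q) + KL(q||p).

    Computed on per-kernel masses after flooring both mass vectors at
    ``KLD_EPS`` and renormalizing, so empty kernels do not produce
    infinities.
    """
    _check_same_grid(p, q)
    pm = np.maximum(p.mass, KLD_EPS)
    qm = np.maximum(q.mass, KLD_EPS)
    pm = pm / pm.sum()
    qm = qm / qm.sum()
    return float(np.sum((pm - qm) * np.log(pm / qm)))


def amrdd_dist(p: DensityEstimate, q: DensityEstimate) -> float:
    """Absolute mean relative difference of two densities.

    mean_i |p_i - q_i| / (0.5 (p_i + q_i)) over the kernel centers; a
    kernel where both densities vanish contributes 0.
    """
    _check_same_grid(p, q)
    a, b = p.density, q.density
    denom = 0.5 * (a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0.0, np.abs(a - b) / denom, 0.0)
    return float(ratio.mean())


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

_ECDF_FUNCS = {
    "ks": ks_stat,
    "kuiper": kuiper_stat,
    "cvm": cvm_stat,
    "ad": ad_stat,
    "wass": wasserstein_stat,
    "dts": dts_stat,
}

_PDF_FUNCS = {
    "euc": euclidean_pdf_dist,
    "kld": kld_sym_dist,
    "amrdd": amrdd_dist,
}


def compare_distributions(
    sample_col,
    full_col,
    metric_id: str,
    grid: Optional[Grid] = None,
    full_pdf: Optional[DensityEstimate] = None,
    smoothing_s: Optional[int] = None,
) -> float:
    """Distance between a sample column and the full data column.

    ECDF metrics act on the raw values; PDF metrics build kernel-density
    estimates on the *full* column's grid (samples are subsets, hence in
    range).  ``grid`` and ``full_pdf`` may be passed to reuse work across
    trials.  A constant full column returns 0 for every metric: a constant
    variable is perfectly preserved by any subset.
    """
    metric = normalize_metric_id(metric_id)
    sample_col = _as_vec(sample_col, "sample_col")
    full_col = _as_vec(full_col, "full_col")
    if full_col.min() == full_col.max():
        return 0.0
    if metric in ECDF_METRICS:
        return _ECDF_FUNCS[metric](sample_col, full_col)
    assert metric in PDF_METRICS
    if grid is None:
        grid = make_grid(full_col)
    kwargs = {} if smoothing_s is None else {"smoothing_s": smoothing_s}
    if full_pdf is None:
        full_pdf = estimate_pdf(full_col, grid, **kwargs)
    sample_pdf = estimate_pdf(sample_col, grid, **kwargs)
    return _PDF_FUNCS[metric](sample_pdf, full_pdf)
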