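"""Synthetic Gaussian-mixture fixtures for sampling experiments.

Two generators emulate the study designs the package is benchmarked on: a
one-dimensional three-class mixture with a dominant broad class, a tiny
needle-like class and a narrow intermediate class (priors [0.6, 0.1, 0.3],
means [0, 4, 6], SDs [2, 0.001, 0.2]); and a 10-variable three-modal data
set whose per-variable component means are drawn uniformly from [1, 100]
and SDs from [1, 30], with class labels assigned in ascending order of the
component means.  A third helper appends far-right integer outliers to a
one-dimensional table to probe how distribution-preserving selection
treats unlabeled extreme values.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .core_io import DataTable

#: 1-D mixture defaults: priors, component means and standard deviations
GMM1D_PRIORS = (0.6, 0.1, 0.3)
GMM1D_MEANS = (0.0, 4.0, 6.0)
GMM1D_SDS = (2.0, 0.001, 0.2)
GMM1D_N_TOTAL = 3000

#: default outliers: 10 consecutive integers starting right of the data range
DEFAULT_OUTLIER_VALUES = tuple(range(15, 25))


@dataclasses.dataclass(frozen=True)
class GmmSpec:
    """One-dimensional Gaussian-mixture specification.

    ``mode`` "priors" draws class memberships multinomially from ``priors``
    (n_total rows in expectation split by the priors); "fixed" uses the
    explicit per-class ``class_counts``.  Both readings of the 1-D design
    are supported because its class sizes can be stated either way
    (equal thirds of 3000, or priors [0.6, 0.1, 0.3] over 3000).
    """

    priors: Sequence[float] = GMM1D_PRIORS
    means: Sequence[float] = GMM1D_MEANS
    sds: Sequence[float] = GMM1D_SDS
    n_total: int = GMM1D_N_TOTAL
    mode: str = "priors"
    class_counts: Optional[Sequence[int]] = None

    def __post_init__(self):
        k = len(self.priors)
        if not (len(self.means) == len(self.sds) == k):
            raise ValueError("priors, means and sds must have equal length")
        if abs(sum(self.priors) - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")
        if self.mode not in ("priors", "fixed"):
            raise ValueError("mode must be 'priors' or 'fixed'")
        if self.mode == "fixed" and self.class_counts is None:
            raise ValueError("fixed mode requires class_counts")
        if self.class_counts is not None and len(self.class_counts) != k:
            raise ValueError("class_counts must match the number of classes")


def generate_gmm1d(spec: GmmSpec, seed: int) -> DataTable:
    """One numeric column plus integer class labels 1..k."""
    rng = np.random.default_rng(int(seed) % (2**63))
    k = len(spec.priors)
    if spec.mode == "fixed":
        cls = np.repeat(np.arange(k), spec.class_counts)
    else:
        cls = rng.choice(k, size=spec.n_total, p=np.asarray(spec.priors, dtype=float))
    means = np.asarray(spec.means, dtype=float)
    sds = np.asarray(spec.sds, dtype=float)
    values = rng.normal(means[cls], sds[cls])
    return DataTable(
        values=values.reshape(-1, 1),
        labels=cls + 1,
        feature_names=("x",),
    )


def generate_gmm_multivar(
    n: int = 30000,
    p: int = 10,
    priors: Sequence[float] = (0.5, 0.4, 0.1),
    mean_range: Sequence[float] = (1.0, 100.0),
    sd_range: Sequence[float] = (1.0, 30.0),
    seed: int = 0,
) -> DataTable:
    """Multivariate three-modal mixture with shared class memberships.

    Each variable gets its own three Gaussian components (means uniform in
    ``mean_range``, SDs uniform in ``sd_range``), sorted ascending by mean
    so class 1 carries the smallest component mean in every variable.  All
    variables share the per-instance class membership drawn from ``priors``.
    """
    if mean_range[0] >= mean_range[1] or sd_range[0] >= sd_range[1]:
        raise ValueError("ranges must be (low, high) with low < high")
    if sd_range[0] <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(int(seed) % (2**63))
    k = len(priors)
    cls = rng.choice(k, size=n, p=np.asarray(priors, dtype=float))
    X = np.empty((n, p))
    for j in range(p):
        means = rng.uniform(mean_range[0], mean_range[1], size=k)
        sds = rng.uniform(sd_range[0], sd_range[1], size=k)
        order = np.argsort(means)
        means, sds = means[order], sds[order]
        X[:, j] = rng.normal(means[cls], sds[cls])
    return DataTable(
        values=X,
        labels=cls + 1,
        feature_names=tuple(f"V{j + 1}" for j in range(p)),
    )


def make_outlier_scenario(
    base: DataTable,
    outlier_values: Optional[Sequence[float]] = None,
    outlier_class=None,
) -> DataTable:
    """Append far-field outliers to a one-column table.

    With ``outlier_class`` given, the outliers form their own class while
    the base keeps its labels (or class 1 when unlabeled).  Without it, all
    class information is merged into a single class — the "hidden
    structure" scenario where downsampling must cope unsupervised.
    """
    if base.p != 1:
        raise ValueError("outlier scenario requires a one-column base table")
    if outlier_values is None:
        outlier_values = DEFAULT_OUTLIER_VALUES
    out = np.asarray(outlier_values, dtype=float)
    values = np.concatenate([base.values.ravel(), out]).reshape(-1, 1)
    n_total = values.shape[0]
    if outlier_class is None:
        labels = np.ones(n_total, dtype=int)
    else:
        base_labels = (
            base.labels if base.labels is not None else np.ones(base.n, dtype=int)
        )
        labels = np.concatenate([base_labels, np.full(out.size, outlier_class)])
    return DataTable(values=values, labels=labels, feature_names=base.feature_names)
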