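"""Representativeness of a sample via PCA reconstruction of the remainder.

A PCA is fitted on the retained sample (centered, unscaled); the removed
rows are projected onto the sample's principal subspace and back, and the
mean squared elementwise error of that round trip,

    MSE = sum_ij (X_reco[i, j] - X_remaining[i, j])^2 / (n p),

quantifies how well the sample's low-dimensional structure explains the
data it left out.  ``evaluate_downsampling`` drives fraction x n_trials
experiment grids with replicated, non-overlapping seed blocks.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, List

import numpy as np
import pandas as pd

from .core_io import DataTable, RunConfig, logger, normalize_metric_id
from .sampler import opdis_downsample

#: component-retention rules: "kaiser" keeps covariance eigenvalues > 1
#: (classical Kaiser-Guttman, appropriate for correlation-scale data);
#: "mean" keeps eigenvalues above the average eigenvalue (the
#: scale-relative form, appropriate when variances are far from 1)
COMPONENT_RULES = ("kaiser", "mean")


@dataclasses.dataclass(frozen=True)
class PCAModel:
    """Centered loadings with retained components of a sample PCA."""

    center: np.ndarray  # length-p training mean
    loadings: np.ndarray  # p x k, orthonormal columns
    eigenvalues: np.ndarray  # k retained eigenvalues, descending
    component_rule: str = "kaiser"
    fallback_applied: bool = False

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclasses.dataclass(frozen=True)
class ReconstructionReport:
    mse: float
    fraction: float
    n_trials: int
    replicate: int
    replicate_seed: int
    metric_id: str
    k_components: int


def fit_pca(sample: DataTable | np.ndarray, component_rule: str = "kaiser") -> PCAModel:
    """Centered, unscaled PCA of the sample with eigenvalue-gated retention.

    ``component_rule`` "kaiser" retains covariance eigenvalues > 1;
    "mean" retains eigenvalues above their average.  When no component
    passes the gate, the first component is kept (logged fallback) so a
    projection always exists.
    """
    if component_rule not in COMPONENT_RULES:
        raise ValueError(f"component_rule must be one of {COMPONENT_RULES}")
    X = np.asarray(getattr(sample, "values", sample), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    threshold = 1.0 if component_rule == "kaiser" else eigvals.mean()
    keep = eigvals > threshold
    fallback = False
    if not keep.any():
        keep = np.zeros_like(keep)
        keep[0] = True
        fallback = True
        logger.info("no eigenvalue above the retention gate; keeping 1 component")
    return PCAModel(
        center=center,
        loadings=eigvecs[:, keep],
        eigenvalues=eigvals[keep],
        component_rule=component_rule,
        fallback_applied=fallback,
    )


def reconstruct(model: PCAModel, x_remaining) -> np.ndarray:
    """Project held-out rows onto the model's principal subspace and back."""
    X = np.asarray(getattr(x_remaining, "values", x_remaining), dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.center.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has p={X.shape[1]}, model p={model.center.shape[0]}"
        )
    scores = (X - model.center) @ model.loadings
    return scores @ model.loadings.T + model.center


def reconstruction_mse(x_reco, x_remaining) -> float:
    """Mean squared elementwise reconstruction error over all n*p cells."""
    a = np.asarray(getattr(x_reco, "values", x_reco), dtype=float)
    b = np.asarray(getattr(x_remaining, "values", x_remaining), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty remaining set")
    return float(np.mean((a - b) ** 2))


def _fraction_to_size(fraction: float, n: int) -> int:
    if not 0.0 < fraction < 1.0:
        raise ValueError("fractions must lie in (0, 1)")
    size = round(fraction * n)
    if size < 1:
        raise ValueError(f"fraction {fraction} yields no instance at n={n}")
    return min(size, n - 1)


def evaluate_downsampling(
    data: DataTable,
    fractions: Iterable[float],
    n_trials_list: Iterable[int],
    n_replicates: int,
    metric_id: str = "ad",
    base_seed: int = 0,
    component_rule: str = "kaiser",
    max_workers: int = 1,
    job_size: int = 10000,
) -> List[ReconstructionReport]:
    """Reconstruction-MSE grid over fraction x n_trials x replicate.

    For each cell: downsample, fit PCA on the retained sample, reconstruct
    the removed remainder and record the MSE.  Replicates use disjoint seed
    blocks (base_seed + replicate * max(n_trials_list)) so no trial seed is
    reused between replicates.
    """
    metric_id = normalize_metric_id(metric_id)
    fractions = list(fractions)
    n_trials_list = list(n_trials_list)
    n_trials_max = max(n_trials_list)
    reports: List[ReconstructionReport] = []
    for replicate in range(n_replicates):
        seed = base_seed + replicate * n_trials_max
        for fraction in fractions:
            size = _fraction_to_size(fraction, data.n)
            for n_trials in n_trials_list:
                config = RunConfig(
                    size=size,
                    seed=seed,
                    n_trials=n_trials,
                    metric_id=metric_id,
                    max_workers=max_workers,
                    job_size=job_size,
                )
                result = opdis_downsample(data, config)
                model = fit_pca(result.sample, component_rule=component_rule)
                mse = reconstruction_mse(
                    reconstruct(model, result.removed), result.removed
                )
                reports.append(
                    ReconstructionReport(
                        mse=mse,
                        fraction=fraction,
                        n_trials=n_trials,
                        replicate=replicate,
                        replicate_seed=seed,
                        metric_id=metric_id,
                        k_components=model.k,
                    )
                )
    return reports


def reports_to_frame(reports: Iterable[ReconstructionReport]) -> pd.DataFrame:
    """Tidy table of an evaluation grid (one row per report)."""
    return pd.DataFrame(
        [
            {
                "fraction": r.fraction,
                "n_trials": r.n_trials,
                "replicate": r.replicate,
                "metric": r.metric_id,
                "k_components": r.k_components,
                "mse": r.mse,
            }
            for r in reports
        ]
    )
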