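"""Seeded class-proportional sampling with min-max distance selection.

The core algorithm: draw many stratified uniform samples (one per trial,
trial seed = base seed + trial index, so the internal seed schedule is
1..n_trials when the base seed is 0), score each trial by the maximum over
variables of a two-sample distribution distance to the full data, and keep
the trial attaining the smallest maximum:

    best sample = argmin over trials of max over variables of
                  distance(sample variable, full variable)

Every instance of a class keeps the same inclusion probability as in plain
stratified uniform sampling — the selection step only picks among draws
that uniform sampling could have produced anyway.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .core_io import DataTable, PDF_METRICS, RunConfig, logger
from .density import estimate_pdf, make_grid


@dataclasses.dataclass(frozen=True)
class TrialResult:
    """One stratified draw and its per-variable distances to the full data."""

    trial_seed: int
    selected_indices: np.ndarray  # sorted, size = config.size
    per_variable_distance: np.ndarray  # length = number of assessed variables
    max_distance: float


@dataclasses.dataclass(frozen=True)
class SamplingResult:
    winner: TrialResult
    sample: DataTable
    removed: DataTable
    config: RunConfig
    n_trials_run: int
    variables_assessed: tuple


def largest_remainder_quotas(counts: np.ndarray, size: int) -> np.ndarray:
    """Apportion ``size`` over classes proportionally to ``counts``.

    Largest-remainder method: floor the exact quotas, then hand the leftover
    units to the classes with the largest fractional remainders (ties toward
    the lower class index).  Guarantees the quotas sum to ``size`` exactly;
    a class may legitimately receive 0.
    """
    counts = np.asarray(counts, dtype=int)
    n = counts.sum()
    exact = size * counts / n
    base = np.floor(exact).astype(int)
    leftover = size - base.sum()
    if leftover > 0:
        frac = exact - base
        order = np.argsort(-frac, kind="stable")
        base[order[:leftover]] += 1
    return base


def stratified_sample_indices(labels, size: int, seed: int) -> np.ndarray:
    """Class-proportional uniform draw of ``size`` row indices.

    Per-class quotas come from largest-remainder apportionment of ``size``
    by class frequencies; within each class the draw is uniform without
    replacement from a generator seeded with ``seed``.  The same seed always
    yields the same index set.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if not 1 <= size < n:
        raise ValueError(f"size must satisfy 1 <= size < n; got size={size}, n={n}")
    classes, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    quotas = largest_remainder_quotas(counts, size)
    rng = np.random.default_rng(int(seed) % (2**63))
    picked = []
    for c in range(classes.size):
        if quotas[c] == 0:
            continue
        members = np.flatnonzero(inverse == c)
        picked.append(rng.choice(members, size=quotas[c], replace=False))
    return np.sort(np.concatenate(picked))


def _precompute_full_columns(data: DataTable, variable_indices, metric_id, smoothing_s):
    """Per-variable full-data artifacts shared by all trials."""
    precomp = []
    for j in variable_indices:
        col = data.values[:, j]
        const = col.min() == col.max()
        grid = pdf = None
        if not const and metric_id in PDF_METRICS:
            grid = make_grid(col)
            kwargs = {} if smoothing_s is None else {"smoothing_s": smoothing_s}
            pdf = estimate_pdf(col, grid, **kwargs)
        precomp.append((j, col, const, grid, pdf))
    return precomp


def _score_indices(data, config, precomp, idx) -> tuple:
    from .distances import compare_distributions

    dists = np.empty(len(precomp))
    for v, (j, col, const, grid, pdf) in enumerate(precomp):
        if const:
            dists[v] = 0.0
        else:
            dists[v] = compare_distributions(
                data.values[idx, j], col, config.metric_id, grid=grid, full_pdf=pdf
            )
    return dists, float(dists.max())


def run_trial(
    data: DataTable,
    config: RunConfig,
    trial_index: int,
    variable_indices: Optional[Sequence[int]] = None,
    _precomp=None,
) -> TrialResult:
    """Execute one seeded trial: trial seed = config.seed + trial_index."""
    if not 1 <= trial_index <= config.n_trials:
        raise ValueError("trial_index must lie in [1, n_trials]")
    if variable_indices is None:
        variable_indices = range(data.p)
    if _precomp is None:
        _precomp = _precompute_full_columns(data, variable_indices, config.metric_id, None)
    trial_seed = config.seed + trial_index
    labels = data.effective_labels()
    idx = stratified_sample_indices(labels, config.size, trial_seed)
    dists, dmax = _score_indices(data, config, _precomp, idx)
    return TrialResult(
        trial_seed=trial_seed,
        selected_indices=idx,
        per_variable_distance=dists,
        max_distance=dmax,
    )


def _best_in_chunk(data, config, precomp, trial_indices) -> TrialResult:
    labels = data.effective_labels()
    best = None
    for t in trial_indices:
        trial_seed = config.seed + t
        idx = stratified_sample_indices(labels, config.size, trial_seed)
        dists, dmax = _score_indices(data, config, precomp, idx)
        if best is None or dmax < best.max_distance:
            best = TrialResult(trial_seed, idx, dists, dmax)
    return best


def select_relevant_features_pca(data: DataTable) -> tuple:
    """PCA-based variable relevance filter.

    Centered, unscaled PCA of the full data; components with covariance
    eigenvalue > 1 are retained, and a variable counts as relevant when its
    contribution to some retained component — 100 * squared loading, since
    loadings are unit vectors — exceeds the uniform expectation 100 / p.
    Returns relevant feature names in original column order; empty when no
    component passes the gate (caller falls back to all variables).
    """
    X = data.values
    if data.p < 2 or data.n < 2:
        return tuple(data.feature_names)
    cov = np.cov(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    retained = eigvals > 1.0
    if not retained.any():
        return ()
    contrib = 100.0 * eigvecs[:, retained] ** 2  # columns are unit vectors
    relevant = (contrib > 100.0 / data.p).any(axis=1)
    return tuple(name for name, keep in zip(data.feature_names, relevant) if keep)


def opdis_downsample(data: DataTable, config: RunConfig) -> SamplingResult:
    """Optimal distribution-preserving downsampling.

    Runs ``config.n_trials`` seeded stratified draws in chunks of
    ``config.job_size`` (chunks may execute in parallel; the result is
    independent of scheduling) and returns the draw whose worst-case
    per-variable distribution distance to the full data is smallest.  Ties
    are broken toward the lowest trial seed.
    """
    config.validate_against(data)
    variable_names = data.feature_names
    if config.pca_importance:
        selected = select_relevant_features_pca(data)
        if selected:
            variable_names = selected
        else:
            logger.warning(
                "PCA importance selected no variables; falling back to all %d",
                data.p,
            )
    name_to_idx = {name: j for j, name in enumerate(data.feature_names)}
    variable_indices = [name_to_idx[name] for name in variable_names]

    precomp = _precompute_full_columns(data, variable_indices, config.metric_id, None)
    chunks = [
        range(start, min(start + config.job_size, config.n_trials) + 1)
        for start in range(1, config.n_trials + 1, config.job_size)
    ]
    n_jobs = min(config.max_workers, len(chunks))
    if n_jobs > 1:
        chunk_best = Parallel(n_jobs=n_jobs)(
            delayed(_best_in_chunk)(data, config, precomp, ch) for ch in chunks
        )
    else:
        chunk_best = [_best_in_chunk(data, config, precomp, ch) for ch in chunks]
    # associative merge: global argmin, ties toward the lowest trial seed
    winner = min(chunk_best, key=lambda t: (t.max_distance, t.trial_seed))

    mask = np.zeros(data.n, dtype=bool)
    mask[winner.selected_indices] = True
    sample = data.take(np.flatnonzero(mask))
    removed = data.take(np.flatnonzero(~mask))
    logger.info(
        "best of %d trials: seed %d, max %s distance %.6g over %d variables",
        config.n_trials, winner.trial_seed, config.metric_id,
        winner.max_distance, len(variable_indices),
    )
    return SamplingResult(
        winner=winner,
        sample=sample,
        removed=removed,
        config=config,
        n_trials_run=config.n_trials,
        variables_assessed=tuple(variable_names),
    )
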