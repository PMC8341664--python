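"""Domain types, tabular I/O and shared configuration.

The central container is :class:`DataTable`, an n x p numeric matrix with
optional per-row class labels — the universe from which class-proportional
samples are drawn.  Tables are read from and written to delimited text
(CSV/TSV with a header row); results of a downsampling run are written as a
sample/removed partition plus a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dpsample")

#: tokens accepted for the distribution-similarity criterion
METRIC_IDS = ("ad", "kuiper", "cvm", "wass", "dts", "ks", "kld", "euc", "amrdd")

#: ECDF-based metrics operate on raw values; the rest on kernel densities
ECDF_METRICS = frozenset({"ad", "kuiper", "cvm", "wass", "dts", "ks"})
PDF_METRICS = frozenset({"kld", "euc", "amrdd"})


def normalize_metric_id(token: str) -> str:
    """Validate a metric token (case-insensitive) and return its canonical form."""
    tok = str(token).strip().lower()
    if tok not in METRIC_IDS:
        raise ValueError(
            f"unknown metric {token!r}; expected one of {', '.join(METRIC_IDS)}"
        )
    return tok


@dataclasses.dataclass(frozen=True)
class DataTable:
    """Numeric matrix with optional class labels.

    Parameters
    ----------
    values
        Real matrix of shape (n, p); no missing entries allowed.
    labels
        Optional length-n sequence of class identifiers.  Absent labels mean
        the whole table is treated as a single class.
    feature_names
        Length-p column identifiers.
    row_ids
        Length-n stable row identifiers (default: 0-based original index),
        preserved through sampling so every output row is auditable.
    """

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    feature_names: Optional[tuple] = None
    row_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values.reshape(-1, 1)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2-D numeric matrix")
        if not np.isfinite(values).all():
            raise ValueError("missing value: NaN/inf entries are not allowed")
        object.__setattr__(self, "values", values)
        n, p = values.shape
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n,):
                raise ValueError(f"labels must have length {n}, got {labels.shape}")
            object.__setattr__(self, "labels", labels)
        names = self.feature_names
        if names is None:
            names = tuple(f"V{j + 1}" for j in range(p))
        else:
            names = tuple(str(x) for x in names)
            if len(names) != p:
                raise ValueError(f"feature_names must have length {p}")
        object.__setattr__(self, "feature_names", names)
        rid = self.row_ids
        if rid is None:
            rid = np.arange(n)
        else:
            rid = np.asarray(rid)
            if rid.shape != (n,):
                raise ValueError(f"row_ids must have length {n}")
        object.__setattr__(self, "row_ids", rid)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def take(self, indices: Sequence[int]) -> "DataTable":
        """Row subset keeping labels, names and row ids aligned."""
        idx = np.asarray(indices, dtype=int)
        return DataTable(
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
            feature_names=self.feature_names,
            row_ids=self.row_ids[idx],
        )

    def effective_labels(self) -> np.ndarray:
        """Labels, or a single-class stand-in when absent."""
        if self.labels is not None:
            return self.labels
        return np.zeros(self.n, dtype=int)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one downsampling run.

    ``size`` is the absolute number of instances to retain; ``seed`` the base
    seed offsetting the internal per-trial seeds 1..n_trials; ``metric_id``
    the distribution-similarity criterion; ``job_size`` the number of trials
    evaluated per chunk; ``pca_importance`` restricts the similarity
    assessment to PCA-relevant variables.
    """

    size: int
    seed: int = 0
    n_trials: int = 1000
    metric_id: str = "ad"
    max_workers: int = 8
    job_size: int = 10000
    pca_importance: bool = False

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("size must be a positive integer")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.job_size < 1:
            raise ValueError("job_size must be >= 1")
        if self.max_workers < 1:
            raise ValueError("max_workers must be >= 1")
        object.__setattr__(self, "metric_id", normalize_metric_id(self.metric_id))

    def validate_against(self, data: DataTable) -> None:
        if self.size >= data.n:
            raise ValueError(
                f"size ({self.size}) must be smaller than the number of "
                f"instances ({data.n})"
            )


def read_table(path: str | os.PathLike, label_column: Optional[str] = None) -> DataTable:
    """Read a CSV/TSV file with header into a :class:`DataTable`.

    The delimiter is inferred from the extension (``.tsv``/``.txt`` -> tab,
    otherwise comma).  If ``label_column`` is given, that column is removed
    from the numeric matrix and stored as class labels; all remaining columns
    must be numeric and complete.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    if df.shape[1] < 1:
        raise ValueError("no numeric value columns in input")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in a value column: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError("missing value in input table")
    return DataTable(values=values, labels=labels, feature_names=tuple(df.columns))


def _table_to_frame(table: DataTable, label_column: str = "cls") -> pd.DataFrame:
    df = pd.DataFrame(table.values, columns=list(table.feature_names))
    if table.labels is not None:
        df[label_column] = table.labels
    df.insert(0, "row_id", table.row_ids)
    return df


def write_result(result, out_prefix: str | os.PathLike) -> dict:
    """Write a sampling result as ``<prefix>.sample.csv``, ``<prefix>.removed.csv``
    and ``<prefix>.report.json``.

    The two CSVs partition the original rows exactly; values are printed at
    full round-trip precision (17 significant digits).  Returns the report
    dictionary.
    """
    prefix = os.fspath(out_prefix)
    sample_path = prefix + ".sample.csv"
    removed_path = prefix + ".removed.csv"
    report_path = prefix + ".report.json"

    _table_to_frame(result.sample).to_csv(
        sample_path, index=False, float_format="%.17g"
    )
    _table_to_frame(result.removed).to_csv(
        removed_path, index=False, float_format="%.17g"
    )
    report = {
        "winning_seed": int(result.winner.trial_seed),
        "metric": result.config.metric_id,
        "size": int(result.config.size),
        "n_trials_run": int(result.n_trials_run),
        "variables_assessed": list(result.variables_assessed),
        "per_variable_distance": {
            name: float(d)
            for name, d in zip(
                result.variables_assessed, result.winner.per_variable_distance
            )
        },
        "max_distance": float(result.winner.max_distance),
        "selected_row_ids": [int(i) for i in result.sample.row_ids],
    }
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info(
        "wrote %s (%d rows), %s (%d rows), %s",
        sample_path, result.sample.n, removed_path, result.removed.n, report_path,
    )
    return report
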