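"""Preprocessing for MS-metabolomics abundance tables.

The pipeline order is fixed: filter sparsely observed features, impute the
remaining missing values, normalise across samples, optionally pool lower
design layers, and finally log-transform. Each step consumes and returns an
:class:`~marrms.design.AbundanceTable` and reports what it removed.

Imputation here is k-nearest-neighbour over feature profiles; other imputers
(e.g. Bayesian PCA, random forest) are deliberately not reimplemented — an
externally imputed matrix can be fed straight into the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .design import AbundanceTable

__all__ = [
    "PreprocessConfig",
    "filter_missing",
    "impute_knn",
    "normalize_quantile",
    "normalize_median",
    "normalize_runday",
    "remove_outlier_samples",
    "log_transform",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing pipeline with field-standard defaults.

    ``max_missing_fraction``: features missing in strictly more than this
    fraction of samples are removed (default 0.2, i.e. the conventional
    "more than 20% missing" rule). ``knn_k``: neighbour count for imputation.
    ``normalization``: one of quantile / median / runday / none.
    ``outlier_z``: drop samples whose median-abundance z-score exceeds this
    in absolute value. ``log_base``: base of the final log transform.
    """

    max_missing_fraction: float = 0.2
    knn_k: int = 5
    normalization: str = "quantile"
    log_transform: bool = True
    log_base: float = 2.0
    outlier_z: float = 3.5

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.normalization not in {"quantile", "median", "runday", "none"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


def _rebuild(table: AbundanceTable, values: pd.DataFrame) -> AbundanceTable:
    return AbundanceTable(
        values=values, coordinates=table.coordinates.loc[values.columns]
    )


def filter_missing(
    table: AbundanceTable, max_missing_fraction: float = 0.2
) -> tuple[AbundanceTable, list]:
    """Drop features missing in strictly more than the allowed fraction.

    A feature missing in exactly the threshold fraction of samples is kept.
    Returns the filtered table and the list of removed feature ids.
    """
    frac = table.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError(
            "filtering removed every feature "
            f"(threshold {max_missing_fraction})"
        )
    removed = table.feature_ids[~keep].tolist()
    return _rebuild(table, table.values.loc[keep]), removed


def impute_knn(table: AbundanceTable, k: int = 5) -> AbundanceTable:
    """Impute missing cells from the k nearest feature profiles.

    Neighbours are features, compared by Euclidean distance over their
    jointly observed samples (distances are rescaled for the number of
    overlapping samples). A missing cell becomes the mean of the neighbours'
    observed values in that sample. Features whose neighbours are all missing
    at a sample — or that overlap no other feature — fall back to their own
    observed mean.
    """
    x = table.values.to_numpy(dtype=float, copy=True)
    mask = np.isnan(x)
    if not mask.any():
        return table
    fully_missing = mask.all(axis=1)
    if fully_missing.any():
        fid = table.feature_ids[fully_missing][0]
        raise ValueError(
            f"feature {fid!r} has no observed values; filter it first"
        )
    need = np.flatnonzero(mask.any(axis=1))
    with np.errstate(invalid="ignore"):
        dist = nan_euclidean_distances(x[need], x)
    own_mean = np.nanmean(x, axis=1)
    m = x.shape[0]
    for row, f in enumerate(need):
        d = dist[row].copy()
        d[f] = np.inf
        d[np.isnan(d)] = np.inf  # no jointly observed samples
        order = np.argsort(d, kind="stable")
        neighbors = order[: min(k, m - 1)]
        neighbors = neighbors[np.isfinite(d[neighbors])]
        for s in np.flatnonzero(mask[f]):
            if neighbors.size:
                vals = x[neighbors, s]
                vals = vals[~np.isnan(vals)]
            else:
                vals = np.empty(0)
            x[f, s] = vals.mean() if vals.size else own_mean[f]
    out = pd.DataFrame(x, index=table.feature_ids, columns=table.sample_ids)
    return _rebuild(table, out)


def normalize_quantile(table: AbundanceTable) -> AbundanceTable:
    """Force every sample onto the common mean quantile distribution.

    The i-th smallest value within each sample is replaced by the mean of the
    i-th smallest values across samples, so all samples share an identical
    sorted value multiset. Within-sample ties all receive the mean of the
    reference values at their tied positions.
    """
    if table.has_missing():
        raise ValueError("quantile normalization requires complete data")
    x = table.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        col = np.empty(x.shape[0])
        col[order[:, j]] = ref
        # average reference values over tied positions within the sample
        vals, inv = np.unique(x[:, j], return_inverse=True)
        if vals.size < x.shape[0]:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[rows, j] = col
    df = pd.DataFrame(out, index=table.feature_ids, columns=table.sample_ids)
    return _rebuild(table, df)


def normalize_median(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample so its median equals the grand median of all values."""
    if table.has_missing():
        raise ValueError("median normalization requires complete data")
    x = table.values
    med = x.median(axis=0)
    if (med == 0).any():
        bad = med.index[med == 0].tolist()
        raise ValueError(f"sample median is zero for: {bad[:5]}")
    grand = float(np.median(x.to_numpy()))
    return _rebuild(table, x / med * grand)


def normalize_runday(table: AbundanceTable, runday: pd.Series) -> AbundanceTable:
    """Correct per-metabolite run-day batch effects.

    Each value is divided by that metabolite's median within its run day and
    multiplied by the metabolite's overall median, removing day-to-day
    instrument tuning drift while preserving between-metabolite scale.
    """
    if table.has_missing():
        raise ValueError("run-day normalization requires complete data")
    runday = pd.Series(runday).reindex(table.sample_ids)
    if runday.isna().any():
        bad = table.sample_ids[runday.isna()].tolist()
        raise ValueError(f"samples without a run-day label: {bad[:5]}")
    x = table.values
    overall = x.median(axis=1)
    out = x.copy()
    for day, cols in x.T.groupby(runday, sort=False).groups.items():
        day_med = x[cols].median(axis=1)
        if (day_med == 0).any():
            feat = day_med.index[day_med == 0][0]
            raise ValueError(
                f"run day {day!r} has zero median for feature {feat!r}"
            )
        out[cols] = x[cols].div(day_med, axis=0).mul(overall, axis=0)
    return _rebuild(table, out)


def remove_outlier_samples(
    table: AbundanceTable, z_threshold: float = 3.5
) -> tuple[AbundanceTable, list]:
    """Drop samples whose median abundance is an outlier across the cohort.

    Each sample's median over features is z-scored against all samples;
    samples with |z| above the threshold are removed. Returns the reduced
    table and the removed sample ids.
    """
    if table.n_samples < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    med = table.values.median(axis=0)
    sd = med.std(ddof=1)
    if sd == 0:
        return table, []
    z = (med - med.mean()) / sd
    drop = z.abs() > z_threshold
    removed = table.sample_ids[drop].tolist()
    if not drop.any():
        return table, []
    return _rebuild(table, table.values.loc[:, ~drop.to_numpy()]), removed


def log_transform(table: AbundanceTable, base: float = 2.0) -> AbundanceTable:
    """Elementwise log in the given base; requires strictly positive values."""
    x = table.values.to_numpy(dtype=float)
    bad = ~(x > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "nonpositive value "
            f"{x[i, j]!r} at feature {table.feature_ids[i]!r}, "
            f"sample {table.sample_ids[j]!r}; log transform needs positives"
        )
    out = pd.DataFrame(
        np.log(x) / np.log(base),
        index=table.feature_ids,
        columns=table.sample_ids,
    )
    return _rebuild(table, out)


def preprocess(
    table: AbundanceTable,
    config: PreprocessConfig = PreprocessConfig(),
    runday: pd.Series | None = None,
    log=None,
) -> AbundanceTable:
    """Run filter -> impute -> normalize (-> log) and report stage counts.

    ``log`` is an optional callable receiving one message per stage. The
    run-day option requires a per-sample ``runday`` label series. Pooling,
    when wanted, happens between normalization and the log transform and is
    orchestrated by the pipeline layer.
    """
    say = log or (lambda msg: None)
    say(f"input: {table.m_features} features x {table.n_samples} samples")
    table, removed = filter_missing(table, config.max_missing_fraction)
    say(
        f"filter(>{config.max_missing_fraction:.0%} missing): removed "
        f"{len(removed)} features, {table.m_features} remain"
    )
    if table.has_missing():
        table = impute_knn(table, config.knn_k)
        say(f"impute: kNN (k={config.knn_k}), no missing cells remain")
    if config.normalization == "quantile":
        table = normalize_quantile(table)
    elif config.normalization == "median":
        table = normalize_median(table)
    elif config.normalization == "runday":
        if runday is None:
            raise ValueError("run-day normalization needs runday labels")
        table = normalize_runday(table, runday)
    say(f"normalize: {config.normalization}")
    if config.log_transform:
        table = log_transform(table, config.log_base)
        say(f"log transform: base {config.log_base:g}")
    return table
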