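"""Intensity preprocessing: quartile-based missingness, prevalence filter,
kNN imputation, median-of-ratios normalization, log2 transform.

The fixed order is: missing mask -> per-group prevalence filter -> kNN
imputation (absent entries only) -> median-ratio normalization -> log2.
Low-intensity observed values below the missingness threshold count as
missing for *filtering* a feature, but once a feature survives the filter
its observed sub-threshold intensities are kept for analysis and are never
imputed over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import DesignTable, IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuartileThresholds:
    """Intensity quartiles of the observed (non-absent) values, raw scale."""

    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.q2 <= self.q3):
            raise ValueError("quartiles must be ordered q1 <= q2 <= q3")


def compute_quartiles(matrix: IntensityMatrix) -> QuartileThresholds:
    """Quartiles of all observed intensities, linear-interpolation convention."""
    observed = matrix.values[~matrix.missing]
    if observed.size < 4:
        raise ValueError("need at least 4 observed intensities to compute quartiles")
    q1, q2, q3 = np.quantile(observed, [0.25, 0.5, 0.75], method="linear")
    return QuartileThresholds(float(q1), float(q2), float(q3))


def build_missing_mask(
    matrix: IntensityMatrix, threshold: float = 0.0, mode: str = "filtering"
) -> np.ndarray:
    """Boolean features x samples mask of entries treated as missing.

    ``filtering`` marks absent entries plus observed entries below
    ``threshold`` (the quartile-censoring rule); ``strict`` marks absent
    entries only and ignores the threshold (the imputation mask).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    absent = matrix.missing
    if mode == "strict":
        return absent
    if mode == "filtering":
        with np.errstate(invalid="ignore"):
            low = matrix.values < threshold
        return absent | (low & ~absent)
    raise ValueError(f"unknown mask mode: {mode!r}")


def filter_by_group_prevalence(
    matrix: IntensityMatrix,
    mask: np.ndarray,
    design: DesignTable,
    min_frac: float = 0.5,
) -> IntensityMatrix:
    """Keep features quantified in >= ``min_frac`` of samples of EVERY condition.

    A feature must clear the prevalence bar in each condition group
    (including the control) to survive.  Surviving features keep all their
    observed values, including those the mask flagged as low-intensity.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != matrix.values.shape:
        raise ValueError("mask shape does not match matrix")
    conditions = np.array(design.aligned_conditions(matrix.sample_ids))
    keep = np.ones(matrix.n_features, dtype=bool)
    for level in design.levels:
        cols = conditions == level
        n = int(cols.sum())
        if n == 0:
            raise ValueError(f"condition {level!r} has no samples in the matrix")
        present = (~mask[:, cols]).sum(axis=1)
        keep &= present / n >= min_frac
    logger.info(
        "prevalence filter (min_frac=%.2f): kept %d / %d features",
        min_frac,
        int(keep.sum()),
        matrix.n_features,
    )
    return matrix.subset_features(keep)


def impute_knn(
    matrix: IntensityMatrix,
    k: int = 10,
    colmax: float = 0.95,
    rowmax: float = 0.5,
) -> IntensityMatrix:
    """Fill absent entries by k-nearest-feature averaging.

    For each feature with absent entries, the k nearest features (Euclidean
    distance over mutually observed samples) that are observed at the target
    sample supply the imputed value as their mean.  Features missing more
    than ``rowmax`` of their samples fall back to their own observed mean.
    A sample missing more than ``colmax`` of its features is a hard error:
    that sample carries too little signal to impute.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.values.copy()
    absent = np.isnan(values)
    if not absent.any():
        return matrix.copy_with(values)

    col_frac = absent.mean(axis=0)
    bad = np.flatnonzero(col_frac > colmax)
    if bad.size:
        names = [matrix.sample_ids[j] for j in bad]
        raise ValueError(
            f"samples exceed colmax={colmax} missing fraction: {names}"
        )

    row_frac = absent.mean(axis=1)
    row_means = np.array([
        np.nanmean(values[i]) if not np.isnan(values[i]).all() else np.nan
        for i in range(values.shape[0])
    ])
    if np.isnan(row_means).any():
        bad_rows = [matrix.feature_ids[i] for i in np.flatnonzero(np.isnan(row_means))]
        raise ValueError(f"features with no observed values cannot be imputed: {bad_rows}")

    out = values.copy()
    fallback = row_frac > rowmax
    for i in np.flatnonzero(fallback & absent.any(axis=1)):
        out[i, absent[i]] = row_means[i]

    todo = np.flatnonzero(~fallback & absent.any(axis=1))
    if todo.size:
        # pairwise Euclidean distances over mutually observed samples
        obs = ~absent
        for i in todo:
            shared = obs[i] & obs  # (n_features, n_samples)
            diff = values[i] - values
            diff[~shared] = 0.0
            n_shared = shared.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                # scale to full-length Euclidean distance as if all were shared
                d2 = (diff**2).sum(axis=1) * values.shape[1] / n_shared
            d2[i] = np.inf
            d2[n_shared == 0] = np.inf
            order = np.argsort(d2, kind="stable")
            for j in np.flatnonzero(absent[i]):
                donors = [n for n in order[: values.shape[0]] if obs[n, j] and np.isfinite(d2[n])]
                donors = donors[:k]
                if donors:
                    out[i, j] = values[donors, j].mean()
                else:
                    out[i, j] = row_means[i]
    if np.isnan(out).any():
        raise RuntimeError("imputation left absent entries")
    return matrix.copy_with(out)


def normalize_median_ratio(
    matrix: IntensityMatrix,
) -> tuple[IntensityMatrix, np.ndarray]:
    """Median-of-ratios normalization.

    Per-feature reference = geometric mean across samples; size factor of
    sample j = median over features of value/reference; each sample is
    divided by its size factor.  Requires a complete, strictly positive
    matrix (imputation precedes this by contract).
    """
    values = matrix.values
    if np.isnan(values).any() or (values <= 0).any():
        raise ValueError("median-ratio normalization needs a complete, positive matrix")
    log_ref = np.mean(np.log(values), axis=1)
    ref = np.exp(log_ref)
    size_factors = np.median(values / ref[:, None], axis=0)
    normalized = values / size_factors[None, :]
    return matrix.copy_with(normalized), size_factors


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Element-wise log2; errors on non-positive entries."""
    values = matrix.values
    if np.isnan(values).any() or (values <= 0).any():
        raise ValueError("log2 transform needs a complete, positive matrix")
    return matrix.copy_with(np.log2(values))


def preprocess_pipeline(
    matrix: IntensityMatrix,
    design: DesignTable,
    censor: str = "none",
    min_frac: float = 0.5,
    knn_k: int = 10,
    colmax: float = 0.95,
    rowmax: float = 0.5,
) -> tuple[IntensityMatrix, dict]:
    """Run the full preprocessing sequence and return (log2 matrix, stage info).

    ``censor`` selects the missingness threshold for filtering: ``none``
    uses the first quartile (lowest quartile treated as missing),
    ``high+medium`` the second, ``high`` the third — reproducing the
    data-censoring schemes at increasing stringency.
    """
    quart = compute_quartiles(matrix)
    threshold = {"none": quart.q1, "high+medium": quart.q2, "high": quart.q3}.get(censor)
    if threshold is None:
        raise ValueError(f"unknown censor scheme: {censor!r}")
    mask = build_missing_mask(matrix, threshold=threshold, mode="filtering")
    filtered = filter_by_group_prevalence(matrix, mask, design, min_frac=min_frac)
    imputed = impute_knn(filtered, k=knn_k, colmax=colmax, rowmax=rowmax)
    normalized, size_factors = normalize_median_ratio(imputed)
    logged = log2_transform(normalized)
    info = {
        "quartiles": {"q1": quart.q1, "q2": quart.q2, "q3": quart.q3},
        "censor": censor,
        "missing_threshold": threshold,
        "n_features_in": matrix.n_features,
        "n_features_kept": filtered.n_features,
        "size_factors": dict(zip(matrix.sample_ids, size_factors.tolist())),
    }
    return logged, info
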