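"""Variance and correlation filtering of fingerprint features.

Two unsupervised filters, applied in sequence on training data only:

1. *Low-variance filter* — drop every column whose population variance
   D(X) = E(X^2) - E(X)^2 falls strictly below a threshold (default 0.05;
   for a binary column this keeps columns whose minority frequency is at
   least ~5.1%).
2. *High-correlation filter* — a greedy left-to-right pass dropping any
   column whose Pearson correlation with an already-kept earlier column
   exceeds a threshold (default 0.7, on |rho| so that complement bits count
   as redundant copies).

The fitted :class:`SelectionMask` is applied unchanged to held-out data, so
no information leaks from validation folds into selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chemio import SchemaError
from .fingerprints import FeatureMatrix

__all__ = ["SelectionConfig", "SelectionMask", "variance_filter",
           "correlation_filter", "fit_selection", "fit_apply"]


@dataclass(frozen=True)
class SelectionConfig:
    variance_threshold: float = 0.05
    correlation_threshold: float = 0.7
    use_absolute_correlation: bool = True

    def __post_init__(self):
        if not (0 < self.variance_threshold <= 1 and 0 < self.correlation_threshold <= 1):
            raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class SelectionMask:
    """Partition of the original feature indices into kept and dropped."""

    kept_indices: list[int]
    dropped_low_variance: list[int] = field(default_factory=list)
    dropped_correlated: list[int] = field(default_factory=list)
    fitted_on: str = ""

    def __post_init__(self):
        all_idx = sorted(self.kept_indices + self.dropped_low_variance
                         + self.dropped_correlated)
        assert all_idx == list(range(len(all_idx))), "index sets must partition 0..p-1"
        assert self.kept_indices == sorted(self.kept_indices)

    @property
    def n_features(self) -> int:
        return (len(self.kept_indices) + len(self.dropped_low_variance)
                + len(self.dropped_correlated))

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if matrix.shape[1] != self.n_features:
            raise SchemaError(
                f"mask fitted on {self.n_features} features, matrix has {matrix.shape[1]}")
        return matrix.select_columns(self.kept_indices)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "SelectionMask":
        text = Path(source).read_text() if isinstance(source, Path) else source
        return cls(**json.loads(text))


def _population_variance(values: np.ndarray) -> np.ndarray:
    return values.var(axis=0, ddof=0)


def variance_filter(matrix: FeatureMatrix, threshold: float = 0.05) -> SelectionMask:
    """Drop columns with population variance strictly below ``threshold``."""
    if matrix.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if matrix.shape[0] == 1:
        warnings.warn("single-row matrix: all variances are 0, every column dropped")
    var = _population_variance(matrix.values)
    kept = [int(i) for i in np.flatnonzero(var >= threshold)]
    dropped = [int(i) for i in np.flatnonzero(var < threshold)]
    return SelectionMask(kept, dropped_low_variance=dropped)


def correlation_filter(matrix: FeatureMatrix, threshold: float = 0.7,
                       use_absolute: bool = True) -> SelectionMask:
    """Greedy left-to-right redundancy pass on Pearson correlations.

    Column j is dropped iff its correlation with some already-kept column
    k < j exceeds ``threshold``. Requires no zero-variance columns (the
    variance filter runs first).
    """
    x = matrix.values
    if np.any(_population_variance(x) == 0):
        raise AssertionError("zero-variance column reached the correlation filter")
    std = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    corr = (std.T @ std) / x.shape[0]
    if use_absolute:
        corr = np.abs(corr)
    kept: list[int] = []
    dropped: list[int] = []
    for j in range(x.shape[1]):
        if kept and np.any(corr[j, kept] > threshold):
            dropped.append(j)
        else:
            kept.append(j)
    return SelectionMask(kept, dropped_correlated=dropped)


def fit_selection(matrix: FeatureMatrix,
                  config: SelectionConfig = SelectionConfig(),
                  fitted_on: str = "") -> SelectionMask:
    """Variance filter then correlation filter, composed into one mask."""
    vmask = variance_filter(matrix, config.variance_threshold)
    if not vmask.kept_indices:
        return SelectionMask([], dropped_low_variance=vmask.dropped_low_variance,
                             fitted_on=fitted_on)
    reduced = matrix.select_columns(vmask.kept_indices)
    cmask = correlation_filter(reduced, config.correlation_threshold,
                               config.use_absolute_correlation)
    kept = [vmask.kept_indices[i] for i in cmask.kept_indices]
    corr_dropped = [vmask.kept_indices[i] for i in cmask.dropped_correlated]
    return SelectionMask(kept, dropped_low_variance=vmask.dropped_low_variance,
                         dropped_correlated=corr_dropped, fitted_on=fitted_on)


def fit_apply(matrix_train: FeatureMatrix, matrix_other: FeatureMatrix | None,
              config: SelectionConfig = SelectionConfig(),
              ) -> tuple[FeatureMatrix, FeatureMatrix | None, SelectionMask]:
    """Fit the mask on training data only and apply it to both matrices."""
    if matrix_other is not None and matrix_train.feature_names != matrix_other.feature_names:
        raise SchemaError("train and other matrices have different feature names")
    mask = fit_selection(matrix_train, config)
    reduced_train = mask.apply(matrix_train)
    reduced_other = mask.apply(matrix_other) if matrix_other is not None else None
    return reduced_train, reduced_other, mask
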