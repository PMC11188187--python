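"""Missingness-aware normalizations.

All four transforms operate column-wise (per sample) over *observed* entries
only, never touch the mask, and preserve labels:

* ``global_median_normalize`` — rescale each sample so its observed median
  equals a target (default 25), the platform's global normalization;
* ``log2_transform``          — log base 2; flips the scale tag;
* ``percentile75_normalize``  — subtract each sample's 75th percentile of
  log2 values (linear-interpolation quantile);
* ``quantile_normalize``      — force all samples onto the rank-wise mean
  reference distribution; with missing data each observed value is mapped
  through its column's empirical quantile onto the reference quantile
  function instead of dropping rows.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import NormalizationError
from .matrix import LINEAR, LOG2, ExpressionMatrix

log = logging.getLogger(__name__)


def global_median_normalize(
    matrix: ExpressionMatrix, target: float = 25.0
) -> ExpressionMatrix:
    """Scale each sample column so its observed median equals ``target``."""
    if matrix.scale != LINEAR:
        raise NormalizationError("global median normalization expects linear scale")
    out = matrix.values.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise NormalizationError(
                f"sample {matrix.sample_ids[c]}: no observed entries"
            )
        med = np.median(observed)
        if med == 0:
            raise NormalizationError(
                f"sample {matrix.sample_ids[c]}: zero median, cannot rescale"
            )
        col *= target / med
    return matrix.with_values(out)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of every observed entry; errors on any observed entry <= 0."""
    values = matrix.values
    bad = np.argwhere(~np.isnan(values) & (values <= 0.0))
    if bad.size:
        r, c = bad[0]
        raise NormalizationError(
            f"log2 undefined for entry <= 0 at "
            f"({matrix.mirna_ids[r]}, {matrix.sample_ids[c]}) = {values[r, c]}"
        )
    return matrix.with_values(np.log2(values), scale=LOG2)


def percentile75_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample column's 75th percentile of observed values.

    Uses the linear-interpolation quantile definition, so afterwards every
    column's observed 75th percentile is 0 (within rounding)."""
    if matrix.scale != LOG2:
        raise NormalizationError("75th-percentile normalization expects log2 scale")
    out = matrix.values.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise NormalizationError(
                f"sample {matrix.sample_ids[c]}: no observed entries"
            )
        col -= np.percentile(observed, 75.0)
    return matrix.with_values(out)


def _reference_quantile(sorted_cols: list[np.ndarray], p: np.ndarray) -> np.ndarray:
    """Mean over columns of each column's linear-interpolation quantile
    function evaluated at probabilities ``p``."""
    acc = np.zeros_like(p, dtype=float)
    for sc in sorted_cols:
        grid = np.linspace(0.0, 1.0, sc.size) if sc.size > 1 else np.array([0.5])
        acc += np.interp(p, grid, sc)
    return acc / len(sorted_cols)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common reference distribution.

    Complete data: the classic rank-mean scheme — sort each column, average
    across columns at each rank, hand values back by original rank; tied
    values receive the mean reference value of their tied span, preserving
    ties.  Missing data: each column's observed values are mapped through
    their empirical quantile (average rank / (n-1)) onto the reference
    quantile function built by averaging per-column quantile functions, so
    masked entries stay masked and nothing is dropped.
    """
    if len(matrix.sample_ids) < 2:
        raise NormalizationError("quantile normalization needs >= 2 sample columns")
    X = matrix.values
    mask = np.isnan(X)
    out = X.copy()
    sorted_cols = []
    for c in range(X.shape[1]):
        observed = X[~mask[:, c], c]
        if observed.size == 0:
            raise NormalizationError(
                f"sample {matrix.sample_ids[c]}: no observed entries"
            )
        sorted_cols.append(np.sort(observed))

    for c in range(X.shape[1]):
        rows = np.flatnonzero(~mask[:, c])
        col = X[rows, c]
        n = col.size
        if n == 1:
            mapped = _reference_quantile(sorted_cols, np.array([0.5]))
        else:
            order = np.argsort(col, kind="stable")
            ranks = np.empty(n, dtype=float)
            ranks[order] = np.arange(n, dtype=float)
            mapped = _reference_quantile(sorted_cols, ranks / (n - 1))
            # ties receive the mean reference value of their tied rank span
            _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
            if (counts > 1).any():
                sums = np.bincount(inv, weights=mapped)
                mapped = (sums / counts)[inv]
        out[rows, c] = mapped
    return matrix.with_values(out)
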