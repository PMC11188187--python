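"""The miRNA x sample expression matrix with an explicit missingness mask.

``ExpressionMatrix`` is the universal currency between QC, imputation,
normalization, batch correction and evaluation.  Missing entries are stored
as NaN in ``values``; the boolean ``mask`` property (True = missing) is
derived from that representation, so observed entries are bit-preserved by
any stage that only touches masked positions.

The ``scale`` tag records whether values are raw linear fluorescence or
log2-transformed; stages check it so that, e.g., a 75th-percentile
subtraction is never applied to linear data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssemblyError

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """miRNA (rows) x sample (columns) value grid with missingness mask.

    Parameters
    ----------
    values : ndarray of float64, shape (n_mirnas, n_samples)
        NaN encodes a missing entry; anything else is an observed value.
    mirna_ids, sample_ids : row / column labels (unique).
    batch_of : mapping sample id -> batch label.
    scale : {"linear", "log2"}
    """

    values: np.ndarray
    mirna_ids: list[str]
    sample_ids: list[str]
    batch_of: dict[str, str] = field(default_factory=dict)
    scale: str = LINEAR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mirna_ids = list(self.mirna_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise AssemblyError("values must be a 2-D grid")
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise AssemblyError(
                f"label counts {(len(self.mirna_ids), len(self.sample_ids))} "
                f"do not match grid shape {self.values.shape}"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise AssemblyError("duplicate miRNA ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AssemblyError("duplicate sample ids")
        if self.scale not in (LINEAR, LOG2):
            raise AssemblyError(f"unknown scale tag {self.scale!r}")

    # -- missingness ------------------------------------------------------

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def row_missing_rate(self) -> np.ndarray:
        return self.mask.mean(axis=1)

    # -- construction helpers --------------------------------------------

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.mirna_ids),
            list(self.sample_ids),
            dict(self.batch_of),
            self.scale,
        )

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Same labels/metadata, new value grid (and optionally a new scale tag)."""
        return ExpressionMatrix(
            values,
            list(self.mirna_ids),
            list(self.sample_ids),
            dict(self.batch_of),
            self.scale if scale is None else scale,
        )

    def subset_rows(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ExpressionMatrix(
            self.values[idx, :],
            [self.mirna_ids[i] for i in idx],
            list(self.sample_ids),
            dict(self.batch_of),
            self.scale,
        )

    def subset_columns(self, sample_ids: list[str]) -> "ExpressionMatrix":
        col = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in col]
        if missing:
            raise AssemblyError(f"unknown sample ids: {missing}")
        idx = [col[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.mirna_ids),
            list(sample_ids),
            {s: self.batch_of[s] for s in sample_ids if s in self.batch_of},
            self.scale,
        )

    def column_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids, columns=self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
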