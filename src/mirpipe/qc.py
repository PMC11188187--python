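"""Quality control and background handling for raw per-spot arrays.

A 3D-Gene-style array reports, per spot, a fluorescence signal, a scanner
quality flag (PASS / NG) and a spot class (PROBE / BLANK).  BLANK spots carry
no probe DNA, so their signals estimate the optical background.  QC proceeds:

1. flag masking — NG probe spots become missing before any arithmetic;
2. background statistics — mean and SD (n-1 denominator) of BLANK signals,
   detection threshold = mean + 2 SD;
3. two derived per-sample columns:
   * *BG subtraction value*: signal - bg_mean for every non-NG probe
     (negative values allowed);
   * *converted value*: signal - bg_mean kept only where signal strictly
     exceeds the detection threshold, missing otherwise (the MNAR mechanism);
4. assembly into miRNA x sample matrices over both batches jointly;
5. removal of miRNAs whose missing rate in the converted matrix strictly
   exceeds 0.95, applied to both matrix variants identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .errors import AssemblyError, QCError
from .matrix import LINEAR, ExpressionMatrix

FLAG_PASS = "PASS"
FLAG_NG = "NG"
CLASS_PROBE = "PROBE"
CLASS_BLANK = "BLANK"


class Spot(NamedTuple):
    probe_id: str
    signal: float  # NaN once flag-masked
    flag: str
    spot_class: str


@dataclass
class RawArray:
    """One sample's per-spot measurements before QC."""

    sample_id: str
    spots: list[Spot]

    def __post_init__(self) -> None:
        probe_ids = [s.probe_id for s in self.spots if s.spot_class == CLASS_PROBE]
        if len(set(probe_ids)) != len(probe_ids):
            raise QCError(f"{self.sample_id}: duplicate probe ids among PROBE spots")

    @property
    def probe_spots(self) -> list[Spot]:
        return [s for s in self.spots if s.spot_class == CLASS_PROBE]

    @property
    def blank_spots(self) -> list[Spot]:
        return [s for s in self.spots if s.spot_class == CLASS_BLANK]

    @property
    def probe_ids(self) -> list[str]:
        return [s.probe_id for s in self.probe_spots]


@dataclass(frozen=True)
class BackgroundStats:
    """Background distribution of one array's BLANK spots."""

    bg_mean: float
    bg_sd: float

    @property
    def threshold(self) -> float:
        """Detection limit: signals at or below bg_mean + 2 SD are missing."""
        return self.bg_mean + 2.0 * self.bg_sd


def compute_background(array: RawArray) -> BackgroundStats:
    """Mean/SD of BLANK-spot signals; SD uses the n-1 (sample) estimator."""
    blanks = np.array([s.signal for s in array.blank_spots], dtype=float)
    if blanks.size < 2:
        raise QCError(
            f"{array.sample_id}: need >=2 BLANK spots to estimate background SD, "
            f"got {blanks.size}"
        )
    return BackgroundStats(bg_mean=float(blanks.mean()), bg_sd=float(blanks.std(ddof=1)))


def apply_flag_mask(array: RawArray) -> RawArray:
    """Return a copy with every NG probe spot's signal replaced by NaN."""
    spots = [
        s._replace(signal=float("nan"))
        if s.spot_class == CLASS_PROBE and s.flag == FLAG_NG
        else s
        for s in array.spots
    ]
    return RawArray(sample_id=array.sample_id, spots=spots)


def bg_subtract(
    array: RawArray, stats: BackgroundStats
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe (bg_subtraction, converted) columns, aligned to ``array.probe_ids``.

    bg_subtraction = signal - bg_mean wherever the signal is present (may be
    negative).  converted = the same difference, kept only where
    signal > threshold ("greater than" is strict; ties are missing).
    NG-masked probes are missing in both columns.
    """
    signal = np.array([s.signal for s in array.probe_spots], dtype=float)
    bg_col = signal - stats.bg_mean
    conv_col = np.where(signal > stats.threshold, bg_col, np.nan)
    return bg_col, conv_col


def assemble_matrix(
    columns: list[tuple[str, list[str], np.ndarray]],
    batch_of: dict[str, str],
    scale: str = LINEAR,
) -> ExpressionMatrix:
    """Stack per-sample columns (sample_id, probe_ids, values) into a matrix.

    All samples must list the same probe ids in the same order; column order
    follows the input order.  NaNs in the columns become masked entries.
    """
    if not columns:
        raise AssemblyError("no sample columns to assemble")
    ref_ids = list(columns[0][1])
    for sample_id, probe_ids, _ in columns:
        if list(probe_ids) != ref_ids:
            raise AssemblyError(
                f"sample {sample_id}: probe-id list differs from first sample"
            )
    values = np.column_stack([np.asarray(v, dtype=float) for _, _, v in columns])
    sample_ids = [c[0] for c in columns]
    return ExpressionMatrix(values, ref_ids, sample_ids, dict(batch_of), scale)


def filter_by_missing_rate(
    matrix: ExpressionMatrix,
    threshold: float = 0.95,
    companions: Iterable[ExpressionMatrix] = (),
) -> tuple[ExpressionMatrix, ...]:
    """Drop miRNAs whose missing fraction strictly exceeds ``threshold``.

    The missing rate is computed on ``matrix`` (pooled over all its sample
    columns, i.e. both batches jointly); the identical row set is removed
    from every companion matrix so the variants stay aligned.
    """
    keep = matrix.row_missing_rate() <= threshold
    out = [matrix.subset_rows(keep)]
    for comp in companions:
        if comp.mirna_ids != matrix.mirna_ids:
            raise AssemblyError("companion matrix rows are not aligned")
        out.append(comp.subset_rows(keep))
    return tuple(out)


def qc_arrays(
    arrays: list[RawArray],
    batch_of: dict[str, str],
    missing_rate_threshold: float = 0.95,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Full QC: flag mask -> background -> subtraction -> assembly -> filter.

    Returns ``(converted, bg_subtraction)`` matrices over all samples, with
    the missing-rate filter computed on the converted matrix and applied to
    both.
    """
    conv_cols, bg_cols = [], []
    for arr in arrays:
        masked = apply_flag_mask(arr)
        stats = compute_background(masked)
        bg_col, conv_col = bg_subtract(masked, stats)
        ids = masked.probe_ids
        conv_cols.append((arr.sample_id, ids, conv_col))
        bg_cols.append((arr.sample_id, ids, bg_col))
    converted = assemble_matrix(conv_cols, batch_of)
    bg_subtraction = assemble_matrix(bg_cols, batch_of)
    converted, bg_subtraction = filter_by_missing_rate(
        converted, missing_rate_threshold, companions=[bg_subtraction]
    )
    return converted, bg_subtraction
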