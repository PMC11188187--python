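"""Plain-text file formats.

* Raw arrays: a tab-separated file per sample with header columns
  ``probe_id  signal  flag  spot_class`` (flag in {PASS, NG}, spot_class in
  {PROBE, BLANK}) — a simplified stand-in dialect for vendor exports, whose
  exact column layout is not public; a ``column_map`` lets users adapt real
  exports.
* Matrices: TSV with probe ids in the first column, sample ids in the
  header, literal ``NA`` for missing; comment lines carry the scale tag and
  batch metadata so the round trip is lossless.

Every writer emits a provenance comment (tool version, seed when known).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import RawParseError, SchemaError
from .matrix import ExpressionMatrix
from .qc import CLASS_BLANK, CLASS_PROBE, FLAG_NG, FLAG_PASS, RawArray, Spot

_RAW_COLUMNS = ("probe_id", "signal", "flag", "spot_class")
_FLAGS = {FLAG_PASS, FLAG_NG}
_CLASSES = {CLASS_PROBE, CLASS_BLANK}


def _provenance(seed=None, extra: str = "") -> str:
    parts = [f"mirpipe {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(extra)
    return "# " + " ".join(parts)


def read_raw_array(path) -> RawArray:
    """Parse one raw per-spot TSV into a :class:`RawArray`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [
        (i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")
    ]
    if not rows:
        raise RawParseError(f"{path}: empty file")
    header_no, header = rows[0]
    cols = header.rstrip("\n").split("\t")
    if tuple(cols) != _RAW_COLUMNS:
        raise SchemaError(
            f"{path}: line {header_no}: expected columns {list(_RAW_COLUMNS)}, got {cols}"
        )
    spots = []
    for lineno, ln in rows[1:]:
        fields = ln.split("\t")
        if len(fields) != 4:
            raise RawParseError(
                f"{path}: line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        probe_id, signal_s, flag, spot_class = fields
        try:
            signal = float(signal_s)
        except ValueError:
            raise RawParseError(
                f"{path}: line {lineno}: signal {signal_s!r} is not a number"
            ) from None
        if flag not in _FLAGS:
            raise SchemaError(
                f"{path}: line {lineno}: flag {flag!r} not in {sorted(_FLAGS)}"
            )
        if spot_class not in _CLASSES:
            raise SchemaError(
                f"{path}: line {lineno}: spot_class {spot_class!r} not in {sorted(_CLASSES)}"
            )
        if signal < 0:
            raise RawParseError(f"{path}: line {lineno}: negative signal {signal}")
        spots.append(Spot(probe_id, signal, flag, spot_class))
    return RawArray(sample_id=path.stem, spots=spots)


def write_raw_array(array: RawArray, path, seed=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(seed, f"sample={array.sample_id}") + "\n")
        fh.write("\t".join(_RAW_COLUMNS) + "\n")
        for s in array.spots:
            fh.write(f"{s.probe_id}\t{s.signal:.6f}\t{s.flag}\t{s.spot_class}\n")


def write_matrix(matrix: ExpressionMatrix, path, seed=None) -> None:
    """Write a matrix TSV; masked entries become literal ``NA``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(seed) + "\n")
        fh.write(f"# scale={matrix.scale}\n")
        if matrix.batch_of:
            pairs = ",".join(f"{s}:{b}" for s, b in matrix.batch_of.items())
            fh.write(f"# batches={pairs}\n")
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, mid in enumerate(matrix.mirna_ids):
            cells = [
                "NA" if np.isnan(v) else repr(float(v)) for v in matrix.values[i]
            ]
            fh.write(mid + "\t" + "\t".join(cells) + "\n")


def read_matrix(path) -> ExpressionMatrix:
    """Read a matrix TSV written by :func:`write_matrix` (lossless round trip)."""
    path = Path(path)
    scale = "linear"
    batch_of: dict[str, str] = {}
    header = None
    data_rows: list[tuple[int, list[str]]] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if body.startswith("scale="):
                scale = body.split("=", 1)[1]
            elif body.startswith("batches="):
                spec = body.split("=", 1)[1]
                if spec:
                    batch_of = dict(p.split(":", 1) for p in spec.split(","))
            continue
        fields = ln.split("\t")
        if header is None:
            if fields[0] != "probe_id":
                raise SchemaError(f"{path}: line {lineno}: first column must be probe_id")
            header = fields[1:]
            continue
        data_rows.append((lineno, fields))
    if header is None:
        raise RawParseError(f"{path}: no header row")
    width = len(header) + 1
    mirna_ids, rows = [], []
    for lineno, fields in data_rows:
        if len(fields) != width:
            raise RawParseError(
                f"{path}: line {lineno}: expected {width} fields, got {len(fields)}"
            )
        mirna_ids.append(fields[0])
        try:
            rows.append(
                [float("nan") if c == "NA" else float(c) for c in fields[1:]]
            )
        except ValueError as exc:
            raise RawParseError(f"{path}: line {lineno}: {exc}") from None
    if len(set(mirna_ids)) != len(mirna_ids):
        dupe = next(m for m in mirna_ids if mirna_ids.count(m) > 1)
        raise RawParseError(f"{path}: duplicate probe id {dupe!r}")
    return ExpressionMatrix(
        np.array(rows, dtype=float), mirna_ids, header, batch_of, scale
    )


def write_truth(truth: pd.DataFrame, path, seed=None) -> None:
    """Write the generator's latent truth grid as a TSV matrix."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(seed, "truth grid (noise-free log2)") + "\n")
        fh.write("probe_id\t" + "\t".join(map(str, truth.columns)) + "\n")
        for mid, row in truth.iterrows():
            fh.write(str(mid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def config_hash(obj) -> str:
    """Short stable hash of a configuration's repr, for provenance lines."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
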