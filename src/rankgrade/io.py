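"""Reading and writing the tool's plain-text interchange formats.

* expression matrix: TSV, first column probe identifiers, first row sample
  identifiers (the top-left header cell may be empty or absent), numeric
  body; LF and CRLF both accepted;
* calls table: one row per sample with the grade, both mean ranks, the
  margin score and coverage counts;
* annotations: per-sample histological grade and survival columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grading import ExpressionMatrix, GradeCall, calls_to_frame

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_calls",
    "read_calls",
    "read_annotations",
]


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probes × samples TSV matrix, validating identifiers and values."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        rows = [i + 2 for i, p in enumerate(frame.index) if p == dup]  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate probe row {dup!r} (lines {rows})")
    try:
        body = frame.astype(float)
    except (TypeError, ValueError):
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                probe = frame.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}"
                ) from None
        raise
    if body.isna().any().any():
        probe = body.index[body.isna().any(axis=1)][0]
        col = body.columns[body.isna().any(axis=0)][0]
        raise ValueError(f"{path}: missing value at probe {probe!r}, sample {col!r}")
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    body.index.name = "probe_id"
    return ExpressionMatrix(body)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV layout `read_matrix` expects."""
    frame = matrix.frame.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def write_calls(calls: list[GradeCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls TSV back into a frame indexed by sample_id."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genomic_grade"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame.set_index("sample_id")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-sample annotations (histo_grade and optionally time/event)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: missing sample_id column")
    if "event" in frame.columns:
        frame["event"] = frame["event"].astype(bool)
    return frame.set_index("sample_id")
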