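"""Strict delimited-text I/O for labeled matrices and parcel vectors.

All interchange is plain tab-delimited text with one header row and row
labels in the first column.  Binary neuroimaging containers are deliberately
not supported; parcel-id keyed vectors are the interchange contract between
stages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_vector", "write_vector", "MatrixParseError"]


class MatrixParseError(ValueError):
    """Raised when a delimited matrix file fails strict parsing."""


def _check_unique(labels, axis_name: str, path) -> None:
    seen = {}
    for pos, lab in enumerate(labels):
        if lab in seen:
            raise MatrixParseError(
                f"{path}: duplicate {axis_name} label {lab!r} "
                f"(positions {seen[lab]} and {pos})"
            )
        seen[lab] = pos


def read_matrix(path, expected_axes: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read a labeled numeric matrix from tab-delimited text.

    The file must have one header row of column labels and row labels in the
    first column.  Parsing is strict: ragged rows, non-numeric cells and
    duplicate labels raise :class:`MatrixParseError` naming the offending
    line or label.

    Parameters
    ----------
    path : path-like
    expected_axes : (n_rows, n_cols), optional
        If given, the parsed shape must match exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header) - 1
        rows, labels = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol + 1:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected {ncol + 1} fields, got {len(parts)}"
                )
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                bad = next(v for v in parts[1:] if not _is_float(v))
                raise MatrixParseError(
                    f"{path}:{lineno}: non-numeric cell {bad!r}"
                ) from None
    _check_unique(labels, "row", path)
    _check_unique(header[1:], "column", path)
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=labels, columns=header[1:])
    if expected_axes is not None and df.shape != tuple(expected_axes):
        raise MatrixParseError(
            f"{path}: shape {df.shape} does not match expected {tuple(expected_axes)}"
        )
    return df


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a labeled matrix as tab-delimited text (full double precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_vector(path) -> pd.Series:
    """Read a two-column (id, value) delimited text file as a Series."""
    df = read_matrix(path)
    if df.shape[1] != 1:
        raise MatrixParseError(f"{path}: expected a single value column, got {df.shape[1]}")
    return df.iloc[:, 0]


def write_vector(values, ids, path, name: str = "value") -> None:
    write_matrix(pd.DataFrame({name: np.asarray(values, float)}, index=list(ids)), path)
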