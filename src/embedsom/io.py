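"""Tabular and cytometry file input/output plus the asinh transform.

All writers are atomic (temp file then rename) and produce output that
round-trips exactly through the matching reader: floats are formatted with
``repr``-style shortest round-trip precision.
"""

from __future__ import annotations

import io as _io
import os
import sys
import tempfile
from typing import Sequence

import numpy as np
import pandas as pd

from ._fcs import FcsError, read_fcs, write_fcs
from .core import PointCloud, ValidationError

__all__ = [
    "read_table",
    "write_table",
    "write_embedding",
    "read_fcs",
    "write_fcs",
    "FcsError",
    "asinh_transform",
]


def read_table(
    path: str | os.PathLike, columns: Sequence[str] | None = None
) -> tuple[PointCloud, list[str]]:
    """Read a CSV/TSV with header into a point cloud.

    The delimiter is sniffed (comma or tab).  All selected columns must be
    numeric; ``columns`` restricts and orders the selection.
    """
    path_s = os.fspath(path)
    if path_s != "-" and not os.path.exists(path_s):
        raise ValidationError(f"input file not found: {path_s}")
    if path_s == "-":
        text = sys.stdin.read()
    else:
        with open(path_s) as fh:
            text = fh.read()
    first = text.split("\n", 1)[0]
    sep = "\t" if "\t" in first else ","
    try:
        # round_trip parsing keeps write->read bit-exact
        df = pd.read_csv(_io.StringIO(text), sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"input table {path_s} is empty") from None
    except pd.errors.ParserError as e:
        raise ValidationError(f"malformed table {path_s}: {e}") from None
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValidationError(
                f"columns {missing} not present; available: {list(df.columns)}"
            )
        df = df[list(columns)]
    if df.shape[0] == 0:
        raise ValidationError(f"table {path_s} has a header but no data rows")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValidationError(
            f"non-numeric columns {bad}; select numeric columns explicitly"
        )
    if df.isna().any().any():
        raise ValidationError(f"table {path_s} contains missing values")
    return PointCloud(df.to_numpy(dtype=np.float64)), [str(c) for c in df.columns]


def _atomic_write_text(path: str, text: str) -> None:
    if path == "-":
        sys.stdout.write(text)
        return
    fd, tmp = tempfile.mkstemp(
        dir=os.path.dirname(os.path.abspath(path)) or ".", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _format_csv(values: np.ndarray, header: Sequence[str]) -> str:
    buf = _io.StringIO()
    buf.write(",".join(header) + "\n")
    for row in np.asarray(values):
        buf.write(",".join(repr(float(v)) for v in row) + "\n")
    return buf.getvalue()


def write_table(
    path: str | os.PathLike, values: np.ndarray, header: Sequence[str]
) -> None:
    """Write a numeric matrix as CSV with full round-trip precision."""
    _atomic_write_text(os.fspath(path), _format_csv(values, header))


def write_embedding(path: str | os.PathLike, coords: np.ndarray) -> None:
    """Write embedded coordinates as CSV with header EmbedSOM1..EmbedSOMP."""
    coords = np.asarray(coords)
    header = [f"EmbedSOM{i + 1}" for i in range(coords.shape[1])]
    write_table(path, coords, header)


def asinh_transform(
    points: PointCloud | np.ndarray, cofactor: float = 5.0
) -> PointCloud:
    """Elementwise ``asinh(x / cofactor)``, the variance-stabilizing
    transform conventional for mass (cofactor 5) and flow (cofactor ~150)
    cytometry intensities."""
    if not cofactor > 0:
        raise ValidationError(f"cofactor must be positive, got {cofactor}")
    X = points.values if isinstance(points, PointCloud) else np.asarray(points, dtype=np.float64)
    return PointCloud(np.arcsinh(X / cofactor))
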