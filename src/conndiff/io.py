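"""Delimited-text I/O for matrices, time series, and run metadata.

The interchange format is plain delimited text (TSV by default, CSV
accepted): an optional first header row of region labels followed by a
square numeric body for matrices, or a time column plus one column per
region for series.  Values are written with 17 significant digits so
write-read round trips are exact.  A sidecar plain-text file may carry
hemisphere tags, one per region.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .network import StructuralNetwork, TimeSeriesData

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_hemisphere_tags",
    "read_network",
    "write_keyvalues",
    "read_keyvalues",
]

_FMT = "%.17g"


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_rows(path: Path):
    path = Path(path)
    delim = _delimiter(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim)]
    rows = [row for row in rows if any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    return rows


def _row_floats(row, path, lineno):
    out = []
    for cell in row:
        try:
            v = float(cell)
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: non-numeric value {cell!r}"
            ) from None
        if np.isnan(v):
            raise ValueError(f"{path}: line {lineno}: NaN entries are forbidden")
        out.append(v)
    return out


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Read a square matrix; returns (values, labels-or-None)."""
    path = Path(path)
    rows = _parse_rows(path)
    labels = None
    start = 0
    try:
        float(rows[0][0])
    except ValueError:
        labels = tuple(cell.strip() for cell in rows[0])
        start = 1
    body = []
    width = None
    for k, row in enumerate(rows[start:], start=start + 1):
        vals = _row_floats(row, path, k)
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise ValueError(
                f"{path}: line {k}: ragged row ({len(vals)} values, expected {width})"
            )
        body.append(vals)
    M = np.array(body, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix body is not square: shape {M.shape}")
    if labels is not None and len(labels) != M.shape[1]:
        raise ValueError(
            f"{path}: header has {len(labels)} labels for {M.shape[1]} columns"
        )
    return M, labels


def write_matrix(matrix, path, labels=None) -> None:
    path = Path(path)
    M = np.asarray(matrix, dtype=float)
    delim = _delimiter(path)
    with open(path, "w", newline="") as fh:
        if labels is not None:
            fh.write(delim.join(labels) + "\n")
        for row in M:
            fh.write(delim.join(_FMT % v for v in row) + "\n")


def read_hemisphere_tags(path) -> tuple[str, ...]:
    """Sidecar file: one hemisphere tag (left/right/none) per line."""
    tags = tuple(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
    bad = set(tags) - {"left", "right", "none"}
    if bad:
        raise ValueError(f"{path}: unknown hemisphere tags {sorted(bad)}")
    return tags


def read_network(path, hemisphere_path=None) -> StructuralNetwork:
    """Read a structural matrix (diagonal stripped) with optional tags."""
    M, labels = read_matrix(path)
    hemi = read_hemisphere_tags(hemisphere_path) if hemisphere_path else None
    return StructuralNetwork.from_sc(M, labels=labels, hemisphere=hemi)


def read_timeseries(path) -> TimeSeriesData:
    """Read a series file: first column time, remaining columns regions."""
    path = Path(path)
    rows = _parse_rows(path)
    labels = None
    start = 0
    try:
        float(rows[0][0])
    except ValueError:
        labels = tuple(cell.strip() for cell in rows[0][1:])
        start = 1
    body = []
    width = None
    for k, row in enumerate(rows[start:], start=start + 1):
        vals = _row_floats(row, path, k)
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise ValueError(
                f"{path}: line {k}: ragged row ({len(vals)} values, expected {width})"
            )
        body.append(vals)
    data = np.array(body, dtype=float)
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError(f"{path}: need a time column, >=1 region, >=2 samples")
    t = data[:, 0]
    dts = np.diff(t)
    if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError(f"{path}: time column must increase at a fixed interval")
    return TimeSeriesData(data[:, 1:], dt=float(dts[0]), labels=labels)


def write_timeseries(ts: TimeSeriesData, path) -> None:
    path = Path(path)
    delim = _delimiter(path)
    with open(path, "w", newline="") as fh:
        if ts.labels is not None:
            fh.write(delim.join(("time",) + ts.labels) + "\n")
        for k, row in enumerate(ts.values):
            cells = [_FMT % (k * ts.dt)] + [_FMT % v for v in row]
            fh.write(delim.join(cells) + "\n")


def write_keyvalues(pairs: dict, path) -> None:
    """Small key=value summary/metadata file."""
    with open(path, "w") as fh:
        for key, val in pairs.items():
            fh.write(f"{key}={val}\n")


def read_keyvalues(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
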