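"""Reading and writing luminance rasters, label rasters and configs.

Luminance maps travel as headerless comma-separated matrices (row-major,
cd/m^2) or as 8/16-bit PGM grayscale images with a linear calibration
(cd/m^2 per gray level, plus an optional offset).  Label matrices use the
same CSV convention with integer entries.  Mapping configurations and scene
parses are JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .photometric import MappingConfig

__all__ = [
    "Calibration",
    "read_luminance",
    "read_labels",
    "write_matrix",
    "read_mapping_config",
]


@dataclass(frozen=True)
class Calibration:
    """Linear gray-level calibration: luminance = gain * level + offset."""

    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"calibration gain must be > 0, got {self.gain}")


def _read_csv_matrix(path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                rows.append([float(x) for x in row])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from None
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}: row {lineno} has {len(rows[-1])} values, "
                    f"expected {len(rows[0])}"
                )
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    return np.asarray(rows, dtype=float)


def read_luminance(
    path,
    fmt: str | None = None,
    calibration: Calibration | None = None,
) -> np.ndarray:
    """Read a strictly positive luminance raster.

    ``fmt`` is 'csv-matrix' or 'pgm'; when omitted it is inferred from the
    file extension ('.pgm' vs anything else).  PGM gray levels are mapped
    through the linear calibration.  Any non-positive luminance is an error
    naming the offending cell.
    """
    path = Path(path)
    if fmt is None:
        fmt = "pgm" if path.suffix.lower() == ".pgm" else "csv-matrix"
    if fmt == "csv-matrix":
        lum = _read_csv_matrix(path)
    elif fmt == "pgm":
        cal = calibration or Calibration()
        levels = np.asarray(iio.imread(path), dtype=float)
        if levels.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel grayscale image")
        lum = cal.gain * levels + cal.offset
    else:
        raise ValueError(f"unknown luminance format {fmt!r}")
    bad = np.argwhere(~(lum > 0) | ~np.isfinite(lum))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-positive luminance {lum[r, c]!r} at row {r}, column {c}"
        )
    return lum


def read_labels(path) -> np.ndarray:
    """Read an integer label matrix (CSV convention)."""
    mat = _read_csv_matrix(path)
    labels = mat.astype(np.int64)
    if not np.array_equal(labels, mat):
        raise ValueError(f"{path}: label matrix contains non-integer entries")
    return labels


def write_matrix(path, array: np.ndarray) -> None:
    """Write a matrix as headerless comma-separated rows."""
    arr = np.asarray(array)
    fmt = "%d" if np.issubdtype(arr.dtype, np.integer) else "%.12g"
    np.savetxt(path, arr, delimiter=",", fmt=fmt)


def read_mapping_config(path) -> MappingConfig:
    """Read a MappingConfig from JSON; missing keys take the defaults."""
    with open(path) as fh:
        return MappingConfig(**json.load(fh))
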