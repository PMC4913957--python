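"""Plain-text grid I/O (ESRI ASCII grid) and small helpers.

All gridded artifacts — hotspot labels, forest masks, annual prediction
layers, decadal accumulations — travel as ESRI ASCII grids (``.asc``): a
six-line header followed by whitespace-separated rows, top row first.  The
format is text, diff-able, and readable by every GIS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_asc", "read_asc"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def write_asc(
    path,
    array: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1000.0,
    nodata: float = -9999,
    fmt: str = "%g",
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost row)."""
    array = np.asarray(array)
    if array.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {array.shape}")
    nrows, ncols = array.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xllcorner:g}\n"
        f"yllcorner {yllcorner:g}\n"
        f"cellsize {cellsize:g}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt=fmt)


def read_asc(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns ``(array, header_dict)``."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key] = float(val)
        array = np.loadtxt(fh)
    array = np.atleast_2d(array)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if array.shape != expect:
        raise ValueError(f"grid shape {array.shape} does not match header {expect}")
    return array, header
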