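"""File I/O: Esri ASCII rasters and CSV tables.

The grid format is the plain-text Esri ASCII raster (``.asc``): a six-line
header (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value)
followed by rows of whitespace-separated values, northernmost row first —
matching the package's row-0-is-north convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def write_esri_ascii(
    path: str | Path,
    grid: np.ndarray,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999,
    fmt: str = "%.6g",
) -> None:
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if grid.dtype == bool:
        grid = grid.astype(np.int8)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {xllcorner:.6g}\n"
        f"yllcorner {yllcorner:.6g}\n"
        f"cellsize {cellsize:.6g}\n"
        f"NODATA_value {nodata:.6g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an Esri ASCII raster; returns (grid, header dict)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0] not in _HEADER_KEYS:
                break
            header[parts[0]] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        grid = np.loadtxt(fh, ndmin=2)
    if "ncols" in header and grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"raster body {grid.shape} does not match header "
            f"({int(header.get('nrows', -1))}, {int(header.get('ncols', -1))})"
        )
    return grid, header


def write_stock_csv(path: str | Path, stock: pd.DataFrame) -> None:
    stock.to_csv(path, index=False, columns=["region_id", "age_class",
                                             "susceptibility", "stock_m3"])


def read_stock_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"region_id", "age_class", "susceptibility", "stock_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stock table missing columns: {sorted(missing)}")
    return df


def write_exposures_csv(path: str | Path, exposures: pd.DataFrame) -> None:
    exposures.to_csv(path, index=True)


def read_exposures_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="region_id")
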