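"""Geographically registered rasters and ESRI ASCII grid text IO.

The in-memory convention is north-up: row 0 is the northernmost row,
``lon0``/``lat0`` are the *center* of the top-left cell, and cell (r, c) has
center ``(lon0 + c * cell_deg, lat0 - r * cell_deg)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    lon0: float  # center of column 0
    lat0: float  # center of row 0 (northernmost)
    cell_deg: float
    values: np.ndarray  # (nrows, ncols), float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not (np.isfinite(self.lon0) and np.isfinite(self.lat0) and self.cell_deg > 0):
            raise ValueError("invalid raster registration")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self):
        """(lon, lat) arrays of shape (nrows, ncols) with cell-center coordinates."""
        lons = self.lon0 + np.arange(self.ncols) * self.cell_deg
        lats = self.lat0 - np.arange(self.nrows) * self.cell_deg
        return np.meshgrid(lons, lats)

    def mask(self) -> np.ndarray:
        """Boolean array, True where a cell holds data."""
        return self.values != self.nodata


def write_ascii_grid(raster: Raster, path) -> Path:
    """Write an ESRI ASCII grid (.asc); xll/yll refer to the grid corner."""
    path = Path(path)
    half = raster.cell_deg / 2.0
    xll = raster.lon0 - half
    yll = raster.lat0 - (raster.nrows - 1) * raster.cell_deg - half
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(raster.cell_deg)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata)!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def read_ascii_grid(path) -> Raster:
    with open(path) as fh:
        header = {}
        while len(header) < 6:
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"ASCII grid body {values.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    lon0 = header["xllcorner"] + cell / 2.0
    lat0 = header["yllcorner"] + cell / 2.0 + (nrows - 1) * cell
    return Raster(lon0=lon0, lat0=lat0, cell_deg=cell, values=values, nodata=header["nodata_value"])
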