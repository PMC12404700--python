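"""Georeferenced single-band rasters in the Esri ASCII grid text format.

Land cover and elevation surfaces are small (tens of km at 50–100 m
cells), so a plain-text grid keeps them portable and diffable. Cells
follow the half-open convention [x0 + i*w, x0 + (i+1)*w): a point on a
shared edge belongs to the cell on its +x / -y side, which makes
nearest-cell sampling bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """Row 0 is the northern (top) row, as in the ASCII grid format."""

    values: np.ndarray          # (nrows, ncols)
    x0: float                   # lower-left corner easting (m)
    y0: float                   # lower-left corner northing (m)
    cell: float                 # cell size (m)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (self.x0, self.y0,
                self.x0 + self.ncols * self.cell,
                self.y0 + self.nrows * self.cell)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def sample(self, x, y):
        """Nearest-cell values at planar points; NaN outside the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell).astype(int)
        row = self.nrows - 1 - row_from_bottom
        out = np.full(x.shape, np.nan)
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        out[ok] = self.values[row[ok], col[ok]]
        out[out == NODATA] = np.nan
        return out

    def write(self, path: str | Path) -> None:
        path = Path(path)
        header = (f"ncols {self.ncols}\nnrows {self.nrows}\n"
                  f"xllcorner {float(self.x0)!r}\nyllcorner {float(self.y0)!r}\n"
                  f"cellsize {float(self.cell)!r}\nNODATA_value {NODATA}\n")
        vals = np.where(np.isnan(self.values), NODATA, self.values)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6g")

    @classmethod
    def read(cls, path: str | Path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError(f"grid shape mismatch in {path}")
        values[values == meta.get("nodata_value", NODATA)] = np.nan
        return cls(values=values, x0=meta["xllcorner"], y0=meta["yllcorner"],
                   cell=meta["cellsize"])
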