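"""Regular raster grids and ESRI ASCII grid I/O.

A :class:`RasterGrid` is a rectangular grid of cell-centred values in the
local metric frame. Row 0 is the *northernmost* row (map order), matching
the ESRI ASCII convention when written with ``yllcorner`` at the bottom.
Depth grids store depth in metres, positive down; derived surfaces (slope,
aspect, stratification, ...) reuse the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """Cell-centred raster on a square grid.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates (m) of the lower-left *corner* of the grid
        (``xllcorner``/``yllcorner`` in ESRI terms).
    cell_size
        Cell edge length in metres (default 50).
    values
        2-D array in map order (row 0 = top/north). ``NaN`` marks nodata
        internally; the sentinel is only used on disk.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        return (
            self.origin_x,
            self.origin_x + self.ncols * self.cell_size,
            self.origin_y,
            self.origin_y + self.nrows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (west→east) and y (south→north) cell centres."""
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D meshes of cell-centre x and y in map order (row 0 = north)."""
        xs, ys = self.cell_centers()
        gx, gy = np.meshgrid(xs, ys[::-1])
        return gx, gy

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin_x, self.origin_y, self.cell_size,
                          np.asarray(values, dtype=float), self.nodata)

    def congruent(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )

    # -- sampling ----------------------------------------------------------

    def sample_bilinear(self, x, y):
        """Bilinear interpolation between cell centres at points ``(x, y)``.

        Returns NaN where any contributing cell is nodata or the point lies
        outside the cell-centre hull.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        xs, ys = self.cell_centers()
        # fractional index in the south-up frame
        fx = (x - xs[0]) / self.cell_size
        fy = (y - ys[0]) / self.cell_size
        out = np.full(x.shape, np.nan)
        inside = (fx >= 0) & (fx <= self.ncols - 1) & (fy >= 0) & (fy <= self.nrows - 1)
        if not inside.any():
            return out if out.size > 1 else float(out[0])
        fxi = np.clip(np.floor(fx[inside]).astype(int), 0, self.ncols - 2)
        fyi = np.clip(np.floor(fy[inside]).astype(int), 0, self.nrows - 2)
        tx = fx[inside] - fxi
        ty = fy[inside] - fyi
        south_up = self.values[::-1]
        v00 = south_up[fyi, fxi]
        v01 = south_up[fyi, fxi + 1]
        v10 = south_up[fyi + 1, fxi]
        v11 = south_up[fyi + 1, fxi + 1]
        val = ((1 - tx) * (1 - ty) * v00 + tx * (1 - ty) * v01
               + (1 - tx) * ty * v10 + tx * ty * v11)
        out[inside] = val
        return out if out.size > 1 else float(out[0])

    def sample_nearest(self, x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_s = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        out = np.full(x.shape, np.nan)
        ok = (col >= 0) & (col < self.ncols) & (row_s >= 0) & (row_s < self.nrows)
        out[ok] = self.values[::-1][row_s[ok], col[ok]]
        return out if out.size > 1 else float(out[0])


def read_ascii_grid(path: str | Path, nodata_default: float = DEFAULT_NODATA) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"missing header field {req!r} in {path}")
    values = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", nodata_default)
    values = np.where(values == nodata, np.nan, values)
    return RasterGrid(header["xllcorner"], header["yllcorner"], header["cellsize"],
                      values, nodata)


def write_ascii_grid(grid: RasterGrid, path: str | Path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid with a bit-compatible header block."""
    path = Path(path)
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {grid.origin_y:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(fmt % v for v in row) + "\n")
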