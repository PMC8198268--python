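"""Single-band raster container with plain-text (ESRI ASCII grid) I/O.

Convention: row 0 is the northern edge, values[row, col]; cell centres are
at x0 + (col + 0.5) * cell, y0 - (row + 0.5) * cell where (x0, y0) is the
north-west corner in a projected coordinate system with metre units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    values: np.ndarray
    x0: float
    y0: float
    cell: float
    crs: str = "local-metre"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= np.isfinite(v)
        return mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of every cell centre, same shape as values."""
        nrows, ncols = self.shape
        x = self.x0 + (np.arange(ncols) + 0.5) * self.cell
        y = self.y0 - (np.arange(nrows) + 0.5) * self.cell
        return np.meshgrid(x, y)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
            and self.crs == other.crs
        )

    def require_aligned(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"misaligned {what}: grids must share shape, origin, cell and crs")

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        return replace(
            self, values=np.asarray(values),
            nodata=self.nodata if nodata is None else nodata,
        )

    def translated(self, dx: float, dy: float) -> "RasterGrid":
        return replace(self, x0=self.x0 + dx, y0=self.y0 + dy)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write as an ESRI ASCII grid (plain text)."""
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {(grid.y0 - nrows * grid.cell)!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fmt = "%d" if grid.values.dtype.kind in "iu" else "%.17g"
        np.savetxt(fh, grid.values, fmt=fmt)


def read_ascii_grid(path, crs: str = "local-metre") -> RasterGrid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nrows = int(hdr["nrows"])
    cell = hdr["cellsize"]
    if values.shape != (nrows, int(hdr["ncols"])):
        raise ValueError("ASCII grid data does not match its header shape")
    return RasterGrid(
        values=values,
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"] + nrows * cell,
        cell=cell,
        crs=crs,
        nodata=hdr.get("nodata_value", DEFAULT_NODATA),
    )
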