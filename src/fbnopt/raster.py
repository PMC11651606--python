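"""In-memory raster grid with ESRI ASCII grid I/O.

A :class:`RasterGrid` is a single-band, axis-aligned, square-cell grid in the
same planar coordinate system as the vector data.  Row 0 is the *top* row
(the ESRI ASCII convention); ``(x0, y0)`` is the lower-left corner of the
grid extent.  Values are nonnegative reals; a ``nodata`` marker (if set) is
honored by all zonal operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    """A square-cell raster in a planar CRS.

    Parameters
    ----------
    x0, y0 : float
        Coordinates of the lower-left corner of the grid extent.
    cell_size : float
        Cell edge length in map units (meters). Must be positive.
    values : ndarray of shape (nrows, ncols)
        Cell values, row 0 at the top. Nonnegative where not nodata.
    nodata : float or None
        Marker for missing cells; ``None`` means every cell is valid.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray = field(repr=False)
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.mask_valid()
        if np.any(self.values[valid] < 0):
            raise ValueError("raster values must be nonnegative (or nodata)")

    # ------------------------------------------------------------------ shape
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    def mask_valid(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.values.shape, dtype=bool)
        return ~np.isclose(self.values, self.nodata)

    # -------------------------------------------------------------- indexing
    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """Rectangle (xmin, ymin, xmax, ymax) of one cell; row 0 is the top row."""
        xmin = self.x0 + col * self.cell_size
        ymax = self.y0 + (self.nrows - row) * self.cell_size
        return (xmin, ymax - self.cell_size, xmin + self.cell_size, ymax)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (cx, cy) of all cell-center coordinates, shaped like values."""
        cx = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        cy = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        return np.meshgrid(cx, cy)

    def window(self, xmin: float, ymin: float, xmax: float, ymax: float
               ) -> tuple[int, int, int, int]:
        """Half-open index window (r0, r1, c0, c1) of cells intersecting a bbox."""
        c0 = int(np.floor((xmin - self.x0) / self.cell_size))
        c1 = int(np.ceil((xmax - self.x0) / self.cell_size))
        gy = self.y0 + self.nrows * self.cell_size  # top edge
        r0 = int(np.floor((gy - ymax) / self.cell_size))
        r1 = int(np.ceil((gy - ymin) / self.cell_size))
        r0 = min(max(r0, 0), self.nrows)
        r1 = min(max(r1, r0), self.nrows)
        c0 = min(max(c0, 0), self.ncols)
        c1 = min(max(c1, c0), self.ncols)
        return (r0, r1, c0, c1)

    def total(self) -> float:
        """Sum of all valid cell values."""
        return float(self.values[self.mask_valid()].sum())


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key!r}")
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"ASCII grid {path}: body shape {body.shape} does not match header"
        )
    return RasterGrid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        values=body,
        nodata=header.get("nodata_value"),
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), deterministic formatting."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x0!r}\n")
        fh.write(f"yllcorner {grid.y0!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        if grid.nodata is not None:
            fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
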