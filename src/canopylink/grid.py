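"""20 m fishnet grid framework.

The grid is the common spatial key joining field plots, lidar cells and
satellite pixels.  Cells are half-open squares ``[x, x+s) x [y, y+s)`` in a
projected metric CRS (x east, y north).  Rows are numbered from the north
(raster convention) and ``cell_id = row * n_cols + col``.  Partial edge
cells are excluded: only full cells inside the extent are part of the
framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridFramework:
    """A regular fishnet of square cells over a rectangular extent."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs: str = "local-metric"

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full-cell coverage."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_rowcol(self, cell_id):
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_center(self, cell_id):
        """Center coordinates of cells; row 0 is the northernmost row."""
        row, col = self.cell_rowcol(cell_id)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_bounds(self, cell_id) -> tuple[float, float, float, float]:
        row, col = self.cell_rowcol(int(cell_id))
        x0 = self.origin_x + col * self.cell_size
        y0 = self.origin_y + (self.n_rows - row - 1) * self.cell_size
        return (x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def point_to_cell(self, x, y):
        """Map points to cell ids; -1 for points outside the framework."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row_s = np.floor((y - self.origin_y) / self.cell_size).astype(np.int64)
        row = self.n_rows - 1 - row_s
        valid = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        ids = np.where(valid, row * self.n_cols + col, -1)
        return ids

    def all_cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells, dtype=np.int64)


def make_fishnet(extent, cell_size: float = 20.0, origin=None) -> GridFramework:
    """Build a grid framework over ``extent`` = (xmin, ymin, xmax, ymax).

    Partial edge cells (where the extent is not an integer multiple of
    ``cell_size``) are excluded.
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    xmin, ymin, xmax, ymax = map(float, extent)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"extent must have positive area, got {extent}")
    if origin is not None:
        xmin, ymin = map(float, origin)
    n_cols = int(np.floor((xmax - xmin) / cell_size + 1e-9))
    n_rows = int(np.floor((ymax - ymin) / cell_size + 1e-9))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("extent smaller than one cell")
    return GridFramework(xmin, ymin, float(cell_size), n_rows, n_cols)
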