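"""Raster data model and coordinate conventions.

A grid is georeferenced by its north-west corner, a square cell size in
metres and a row/column count.  Row 0 is the northernmost row; cell values
represent the quantity of the whole cell.  Point queries use half-open cell
intervals: a cell owns ``[edge, edge + cell_size)`` going east and south, so
every point strictly inside the extent belongs to exactly one cell.

All computation is done in 64-bit floating point; large buffer sums
accumulate millions of terms and 32-bit accumulation drifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "Raster", "DEFAULT_NODATA"]

#: NODATA sentinel used when writing files that need one (e.g. ESRI ASCII).
DEFAULT_NODATA = -9999.0

#: EPSG codes of common geographic (degree-unit) systems, rejected because
#: every operation here assumes a projected CRS with metre units.
_GEOGRAPHIC_EPSG = {4326, 4258, 4269, 4283, 4617, 4937, 4979}


@dataclass(frozen=True)
class GridSpec:
    """Georeferenced raster geometry on a projected, metric CRS.

    Parameters
    ----------
    x_min : float
        Easting of the west edge (metres).
    y_max : float
        Northing of the north edge (metres).
    cell_size : float
        Square cell edge length (metres), > 0.
    n_rows, n_cols : int
        Grid dimensions, >= 1.
    crs_label : str
        Opaque CRS label, e.g. ``"EPSG:28992"`` (Amersfoort / RD New,
        the Dutch national system).  Only checked for being projected;
        no reprojection is ever performed.
    """

    x_min: float
    y_max: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "EPSG:28992"

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid must have at least one row and column, got "
                f"{self.n_rows}x{self.n_cols}"
            )
        code = self.epsg_code()
        if code is not None and code in _GEOGRAPHIC_EPSG:
            raise ValueError(
                f"{self.crs_label} is a geographic CRS; a projected CRS with "
                "metre units is required"
            )

    # -- derived geometry -------------------------------------------------

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def epsg_code(self) -> int | None:
        """Parse an ``EPSG:<int>`` label; None if the label is free-form."""
        label = self.crs_label.strip().upper()
        if label.startswith("EPSG:"):
            try:
                return int(label[5:])
            except ValueError:
                return None
        return None

    # -- coordinate transforms -------------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of the centre of cell (row, col).

        Distances and point extractions are all defined against cell
        centre coordinates.
        """
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(
                f"cell ({row}, {col}) outside grid of shape {self.shape}"
            )
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_max - (row + 0.5) * self.cell_size
        return (x, y)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised centre coordinates: (xs[n_cols], ys[n_rows])."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y).

        Cells are half-open: the west and north edges belong to the cell,
        the east and south edges to its neighbour.
        """
        col = math.floor((x - self.x_min) / self.cell_size)
        row = math.floor((self.y_max - y) / self.cell_size)
        # north/west domain edges are inclusive, south/east exclusive
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(
                f"point ({x}, {y}) outside grid extent "
                f"[{self.x_min}, {self.x_max}) x ({self.y_min}, {self.y_max}]"
            )
        return (row, col)

    def contains_point(self, x: float, y: float) -> bool:
        return (self.x_min <= x < self.x_max) and (self.y_min < y <= self.y_max)

    def same_geometry(self, other: "GridSpec") -> bool:
        """Geometric equality ignoring the CRS label string."""
        return (
            self.x_min == other.x_min
            and self.y_max == other.y_max
            and self.cell_size == other.cell_size
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )


@dataclass
class Raster:
    """A grid spec plus a 2-D float64 value array and a NODATA mask.

    NODATA is carried as a boolean mask rather than a sentinel value so
    that no sentinel can ever leak into an aggregation; the sentinel is
    only materialised when writing files.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise ValueError("mask shape does not match grid shape")

    # -- constructors -----------------------------------------------------

    @classmethod
    def full(cls, spec: GridSpec, value: float) -> "Raster":
        return cls(spec, np.full(spec.shape, value, dtype=np.float64))

    @classmethod
    def zeros(cls, spec: GridSpec) -> "Raster":
        return cls.full(spec, 0.0)

    # -- accessors --------------------------------------------------------

    @property
    def has_nodata(self) -> bool:
        return bool(self.mask.any())

    def filled(self, fill: float | None = None) -> np.ndarray:
        """Values with NODATA cells replaced by the sentinel (or ``fill``)."""
        out = self.values.copy()
        out[self.mask] = self.nodata if fill is None else fill
        return out

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); NaN for a NODATA cell."""
        row, col = self.spec.point_to_cell(x, y)
        if self.mask[row, col]:
            return float("nan")
        return float(self.values[row, col])

    # -- whole-raster operations -----------------------------------------

    def crop(self, row_start: int, row_stop: int, col_start: int, col_stop: int) -> "Raster":
        """Sub-raster of rows [row_start, row_stop), cols [col_start, col_stop).

        Georeferencing of the retained cells is preserved.
        """
        if not (0 <= row_start < row_stop <= self.spec.n_rows):
            raise ValueError(f"row window [{row_start}, {row_stop}) outside grid")
        if not (0 <= col_start < col_stop <= self.spec.n_cols):
            raise ValueError(f"col window [{col_start}, {col_stop}) outside grid")
        spec = replace(
            self.spec,
            x_min=self.spec.x_min + col_start * self.spec.cell_size,
            y_max=self.spec.y_max - row_start * self.spec.cell_size,
            n_rows=row_stop - row_start,
            n_cols=col_stop - col_start,
        )
        return Raster(
            spec,
            self.values[row_start:row_stop, col_start:col_stop].copy(),
            self.mask[row_start:row_stop, col_start:col_stop].copy(),
            nodata=self.nodata,
        )

    def resample(self, factor: int, mode: str = "mean") -> "Raster":
        """Aggregate ``factor`` x ``factor`` blocks of cells into one.

        ``mode='sum'`` for additive quantities (lengths, loads, counts),
        ``mode='mean'`` for intensive quantities (concentrations).  The grid
        dimensions must be divisible by the factor.  NODATA cells are
        excluded; a block that is entirely NODATA stays NODATA.
        """
        if factor < 1 or int(factor) != factor:
            raise ValueError(f"factor must be a positive integer, got {factor}")
        factor = int(factor)
        if self.spec.n_rows % factor or self.spec.n_cols % factor:
            raise ValueError(
                f"grid shape {self.spec.shape} not divisible by factor {factor}"
            )
        if mode not in ("sum", "mean"):
            raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
        nr, nc = self.spec.n_rows // factor, self.spec.n_cols // factor
        vals = np.where(self.mask, 0.0, self.values)
        blocks = vals.reshape(nr, factor, nc, factor)
        valid = (~self.mask).reshape(nr, factor, nc, factor)
        total = blocks.sum(axis=(1, 3))
        count = valid.sum(axis=(1, 3))
        out_mask = count == 0
        if mode == "sum":
            out = total
        else:
            out = np.divide(total, count, out=np.zeros_like(total), where=~out_mask)
        spec = replace(
            self.spec,
            cell_size=self.spec.cell_size * factor,
            n_rows=nr,
            n_cols=nc,
        )
        return Raster(spec, out, out_mask, nodata=self.nodata)

    # -- arithmetic (NODATA propagates) ----------------------------------

    def _binary(self, other: "Raster", op) -> "Raster":
        if not self.spec.same_geometry(other.spec):
            raise ValueError("raster grids do not match")
        return Raster(
            self.spec,
            op(self.values, other.values),
            self.mask | other.mask,
            nodata=self.nodata,
        )

    def __add__(self, other: "Raster") -> "Raster":
        return self._binary(other, np.add)

    def __sub__(self, other: "Raster") -> "Raster":
        return self._binary(other, np.subtract)

    def scaled(self, factor: float) -> "Raster":
        return Raster(self.spec, self.values * factor, self.mask.copy(), self.nodata)
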