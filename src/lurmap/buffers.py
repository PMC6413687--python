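"""Circular-buffer and annulus focal sums over rasters.

Every buffered LUR predictor (POP_5000, TL_50, HTL_25-500, ...) is a focal
sum: the value at a cell is the sum of a per-cell quantity over all cells
whose centres lie within the given radius of the focal cell's centre.
Membership uses a closed comparison (distance <= radius), decided in exact
rational arithmetic so ties like the (3,4,5) triangle at radius 25 m on a
5 m grid are included deterministically: the 25 m kernel is the classic
81-cell disk.

Cells outside the grid contribute zero (zero padding) — buffer sums near
the border are therefore underestimates, which mirrors working at a
national boundary with no data from neighbouring countries.  NODATA input
cells contribute zero but are tracked: a neighbourhood containing no valid
cell yields NODATA.

Two computation paths produce bit-identical results per kernel:

* small kernels: shifted-array accumulation over kernel offsets in sorted
  (drow, dcol) order — per cell this is the plain sequential sum a
  brute-force loop over the same sorted offsets would produce, bitwise;
* large kernels: per-kernel-row sliding-window sums from per-row prefix
  sums, accumulated over kernel rows in fixed order.  Each output row
  depends only on whole input rows, so processing the grid in horizontal
  bands (tiling) reproduces the untiled result bit for bit.

The path is chosen from the kernel size alone, so a given radius always
takes the same path regardless of tiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import isqrt

import numpy as np

from .grid import Raster

__all__ = [
    "BufferKernel",
    "make_kernel",
    "make_annulus_kernel",
    "focal_sum",
    "annulus_sum",
    "BufferedPredictor",
    "compute_predictor_stack",
]

#: Kernels with at most this many member cells use the shifted-array
#: (oracle-order) path; larger kernels use the sliding-window path.
EXACT_OFFSET_LIMIT = 10_000


@dataclass(frozen=True)
class BufferKernel:
    """A circular (or annular) set of cell offsets around a focal cell.

    ``runs[i]`` lists the inclusive column-offset intervals belonging to
    row offset ``row_offsets[i]``; a disk has one run per row, an annulus
    one or two.
    """

    radius: float
    cell_size: float
    inner_radius: float | None
    row_offsets: tuple[int, ...]
    runs: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_cells(self) -> int:
        return sum(hi - lo + 1 for row in self.runs for (lo, hi) in row)

    def offsets(self) -> list[tuple[int, int]]:
        """All (drow, dcol) members in sorted order."""
        out = []
        for di, row in zip(self.row_offsets, self.runs):
            for lo, hi in row:
                out.extend((di, dj) for dj in range(lo, hi + 1))
        return out

    def max_row_extent(self) -> int:
        return max(abs(d) for d in self.row_offsets) if self.row_offsets else 0


def _half_width(i: int, q2: Fraction) -> int:
    """Largest j >= 0 with i^2 + j^2 <= q2 (exact), or -1 if none."""
    rem = q2 - i * i
    if rem < 0:
        return -1
    return isqrt(int(rem))  # j^2 <= rem  <=>  j^2 <= floor(rem) for integer j


def make_kernel(radius: float, cell_size: float) -> BufferKernel:
    """Disk kernel: offsets whose centre distance is <= radius.

    Always contains the focal cell itself for radius >= 0.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    q2 = (Fraction(radius) / Fraction(cell_size)) ** 2
    k = isqrt(int(q2))
    row_offsets, runs = [], []
    for di in range(-k, k + 1):
        w = _half_width(di, q2)
        if w >= 0:
            row_offsets.append(di)
            runs.append(((-w, w),))
    return BufferKernel(radius, cell_size, None, tuple(row_offsets), tuple(runs))


def make_annulus_kernel(r_inner: float, r_outer: float,
                        cell_size: float) -> BufferKernel:
    """Ring kernel: offsets with r_inner < centre distance <= r_outer."""
    if not 0 <= r_inner < r_outer:
        raise ValueError(
            f"need 0 <= r_inner < r_outer, got {r_inner}, {r_outer}"
        )
    q2_out = (Fraction(r_outer) / Fraction(cell_size)) ** 2
    q2_in = (Fraction(r_inner) / Fraction(cell_size)) ** 2
    k = isqrt(int(q2_out))
    row_offsets, runs = [], []
    for di in range(-k, k + 1):
        w_out = _half_width(di, q2_out)
        if w_out < 0:
            continue
        w_in = _half_width(di, q2_in)  # -1 if the row misses the inner disk
        if w_in < 0:
            row = ((-w_out, w_out),)
        elif w_in >= w_out:
            continue  # entire row swallowed by the inner disk
        else:
            row = ((-w_out, -w_in - 1), (w_in + 1, w_out))
        row_offsets.append(di)
        runs.append(row)
    return BufferKernel(r_outer, cell_size, r_inner,
                        tuple(row_offsets), tuple(runs))


# ------------------------------------------------------------ focal engine

def _focal_shift_band(values: np.ndarray, kernel: BufferKernel,
                      r0: int, r1: int) -> np.ndarray:
    """Output rows [r0, r1) by shifted-array accumulation.

    Per output cell the additions happen in sorted (drow, dcol) offset
    order with out-of-grid cells skipped (contributing zero) — bitwise the
    same sequence a sequential per-cell brute-force loop produces, and
    independent of the band split.
    """
    n, m = values.shape
    out = np.zeros((r1 - r0, m), dtype=np.float64)
    for di, dj in kernel.offsets():
        a0, a1 = max(r0 + di, 0), min(r1 + di, n)
        if a0 >= a1:
            continue
        b0, b1 = a0 - di - r0, a1 - di - r0
        c0, c1 = max(0, -dj), min(m, m - dj)
        if c0 < c1:
            out[b0:b1, c0:c1] += values[a0:a1, c0 + dj:c1 + dj]
    return out


def _focal_runs_band(values: np.ndarray, kernel: BufferKernel,
                     r0: int, r1: int) -> np.ndarray:
    """Output rows [r0, r1) by per-kernel-row sliding-window sums.

    Row sums come from per-row prefix sums (row-local, so identical
    whatever the band split); kernel rows accumulate in fixed order.
    """
    n, m = values.shape
    # per-row prefix sums with a leading zero: P[r, k] = sum(values[r, :k])
    prefix = np.zeros((n, m + 1), dtype=np.float64)
    np.cumsum(values, axis=1, out=prefix[:, 1:])
    cols = np.arange(m)
    out = np.zeros((r1 - r0, m), dtype=np.float64)
    for di, row_runs in zip(kernel.row_offsets, kernel.runs):
        a0, a1 = max(r0 + di, 0), min(r1 + di, n)
        if a0 >= a1:
            continue
        b0, b1 = a0 - di - r0, a1 - di - r0
        p = prefix[a0:a1]
        for lo, hi in row_runs:
            idx_hi = np.clip(cols + hi + 1, 0, m)
            idx_lo = np.clip(cols + lo, 0, m)
            out[b0:b1] += p[:, idx_hi] - p[:, idx_lo]
    return out


def _focal_values(values: np.ndarray, kernel: BufferKernel,
                  tile_rows: int | None) -> np.ndarray:
    n = values.shape[0]
    band = _focal_shift_band if kernel.n_cells <= EXACT_OFFSET_LIMIT \
        else _focal_runs_band
    if tile_rows is None:
        return band(values, kernel, 0, n)
    if tile_rows < 1:
        raise ValueError(f"tile_rows must be >= 1, got {tile_rows}")
    return np.concatenate([
        band(values, kernel, r0, min(n, r0 + tile_rows))
        for r0 in range(0, n, tile_rows)
    ])


def _focal_raster(raster: Raster, kernel: BufferKernel,
                  tile_rows: int | None) -> Raster:
    vals = np.where(raster.mask, 0.0, raster.values) if raster.has_nodata \
        else raster.values
    out = _focal_values(vals, kernel, tile_rows)
    if raster.has_nodata:
        valid = (~raster.mask).astype(np.float64)
        count = _focal_values(valid, kernel, tile_rows)
        mask = count == 0.0
    else:
        mask = np.zeros_like(raster.mask)
    return Raster(raster.spec, out, mask, nodata=raster.nodata)


def focal_sum(raster: Raster, radius: float,
              tile_rows: int | None = None) -> Raster:
    """Sum of cell values within ``radius`` metres of every cell centre."""
    kernel = make_kernel(radius, raster.spec.cell_size)
    return _focal_raster(raster, kernel, tile_rows)


def annulus_sum(raster: Raster, r_inner: float, r_outer: float,
                tile_rows: int | None = None) -> Raster:
    """Sum over the ring r_inner < distance <= r_outer, computed with a
    ring kernel directly (not as a difference of two disk sums), so the
    result is exactly the sum over the ring cells."""
    kernel = make_annulus_kernel(r_inner, r_outer, raster.spec.cell_size)
    return _focal_raster(raster, kernel, tile_rows)


# ------------------------------------------------------- predictor stacks

@dataclass
class BufferedPredictor:
    """A buffered predictor map, e.g. POP_5000 or the annulus HTL_25-500."""

    raster: Raster
    predictor_id: str
    buffer: float | tuple[float, float]

    @property
    def key(self) -> str:
        return buffer_key(self.predictor_id, self.buffer)


def buffer_key(predictor_id: str, buffer) -> str:
    """Canonical name of a buffered predictor: 'POP_5000', 'HTL_25-500'."""
    if buffer is None:
        return predictor_id
    if isinstance(buffer, tuple):
        rin, rout = buffer
        return f"{predictor_id}_{_fmt(rin)}-{_fmt(rout)}"
    return f"{predictor_id}_{_fmt(buffer)}"


def _fmt(r: float) -> str:
    return str(int(r)) if float(r).is_integer() else str(r)


def compute_predictor_stack(
    predictor_rasters: dict[str, "PredictorRaster | Raster"],
    required_terms: list[tuple[str, float | tuple[float, float]]],
    tile_rows: int | None = None,
) -> dict[str, BufferedPredictor]:
    """Compute every required buffered predictor exactly once.

    ``required_terms`` is a list of (predictor_id, buffer) pairs where the
    buffer is a radius in metres or an (inner, outer) annulus; duplicates
    (e.g. POP_5000 appearing in three models) are computed once.
    """
    out: dict[str, BufferedPredictor] = {}
    for pid, buffer in required_terms:
        key = buffer_key(pid, buffer)
        if key in out:
            continue
        if pid not in predictor_rasters:
            raise ValueError(
                f"no base raster for predictor {pid!r} (needed for {key})"
            )
        base = predictor_rasters[pid]
        raster = base.raster if hasattr(base, "raster") else base
        if isinstance(buffer, tuple):
            summed = annulus_sum(raster, buffer[0], buffer[1], tile_rows)
        else:
            summed = focal_sum(raster, float(buffer), tile_rows)
        out[key] = BufferedPredictor(summed, pid, buffer)
    return out
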