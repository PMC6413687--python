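"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the most literal method available
(per-cell loops, dense sampling, direct weighted sums) so they share no
code with the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _brute_focal(values, drows, dcols):
    """Sequential per-cell double loop over kernel offsets (sorted order);
    out-of-grid neighbours contribute zero."""
    n, m = values.shape
    out = np.zeros((n, m))
    for r in range(n):
        for c in range(m):
            s = 0.0
            for k in range(drows.size):
                rr = r + drows[k]
                cc = c + dcols[k]
                if 0 <= rr < n and 0 <= cc < m:
                    s += values[rr, cc]
            out[r, c] = s
    return out


def brute_force_focal(values: np.ndarray, offsets) -> np.ndarray:
    """Focal sum by brute force for a list of (drow, dcol) offsets."""
    off = np.asarray(offsets, dtype=np.int64)
    return _brute_focal(np.asarray(values, dtype=np.float64),
                        off[:, 0].copy(), off[:, 1].copy())


def disk_offsets(radius: float, cell_size: float):
    """Kernel membership re-derived independently: centre distance <= radius,
    enumerated by scanning a bounding square."""
    k = int(np.ceil(radius / cell_size)) + 1
    out = []
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            if (di * cell_size) ** 2 + (dj * cell_size) ** 2 <= radius ** 2:
                out.append((di, dj))
    return out


def annulus_offsets(r_inner: float, r_outer: float, cell_size: float):
    inner = set(disk_offsets(r_inner, cell_size))
    return [o for o in disk_offsets(r_outer, cell_size) if o not in inner]


def dense_sample_lengths(spec, coords, step=0.001) -> np.ndarray:
    """Per-cell lengths of a polyline estimated by sampling it at ``step``
    metre intervals and binning the sample points."""
    out = np.zeros(spec.shape)
    c = np.asarray(coords, dtype=np.float64)
    for (x0, y0), (x1, y1) in zip(c[:-1], c[1:]):
        length = float(np.hypot(x1 - x0, y1 - y0))
        if length == 0:
            continue
        n = max(1, int(round(length / step)))
        t = (np.arange(n) + 0.5) / n
        xs = x0 + t * (x1 - x0)
        ys = y0 + t * (y1 - y0)
        inside = ((xs >= spec.x_min) & (xs < spec.x_max)
                  & (ys > spec.y_min) & (ys <= spec.y_max))
        cols = ((xs[inside] - spec.x_min) // spec.cell_size).astype(int)
        rows = ((spec.y_max - ys[inside]) // spec.cell_size).astype(int)
        np.add.at(out, (rows, cols), length / n)
    return out


def point_segment_distance(px, py, ax, ay, bx, by) -> float:
    """Scalar point-to-segment distance from first principles."""
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0.0:
        return float(np.hypot(px - ax, py - ay))
    t = ((px - ax) * dx + (py - ay) * dy) / L2
    t = min(1.0, max(0.0, t))
    return float(np.hypot(px - (ax + t * dx), py - (ay + t * dy)))


def brute_idw(x, y, coords, values, radius, power):
    """Direct weighted sum at one point; None where no station in range."""
    num = den = 0.0
    for (sx, sy), v in zip(coords, values):
        d = float(np.hypot(x - sx, y - sy))
        if d > radius:
            continue
        if d == 0.0:
            return float(v)
        w = d ** (-power)
        num += w * v
        den += w
    if den == 0.0:
        return None
    return num / den
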