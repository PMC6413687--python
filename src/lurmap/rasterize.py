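"""Vector-to-raster conversion of the LUR predictor inputs.

Per-cell quantities produced here are the *unbuffered* predictors:

====  ==========================================  =====================
id    meaning                                     per-cell units
====  ==========================================  =====================
RL    road length, all roads                      m
MRL   road length, major roads                    m
TL    traffic load, all roads                     vehicles day^-1 m
TML   traffic load, major roads                   vehicles day^-1 m
HTL   heavy-traffic load, all roads               vehicles day^-1 m
IND   industrial area                             m^2
HAR   harbour area                                m^2
RES   residential area                            m^2
POP   population                                  inhabitants
====  ==========================================  =====================

Road segments are clipped to cell rectangles exactly (parametric grid
traversal), so the per-cell lengths sum to the total network length inside
the grid extent to machine precision.  Polygon predictors use cell-centre
membership (the gdal_rasterize convention): a 5 m cell is either fully in a
class (25 m^2) or not at all.  Population counts are spread uniformly over
the cells covered by each zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely

from .grid import GridSpec, Raster
from .vector import LandUseLayer, PopulationLayer, RoadNetwork, RoadSegment

__all__ = [
    "PredictorRaster",
    "PREDICTOR_UNITS",
    "rasterize_line_length",
    "rasterize_traffic_load",
    "rasterize_class_area",
    "rasterize_population",
]

PREDICTOR_UNITS = {
    "RL": "m",
    "MRL": "m",
    "TL": "vehicles day-1 m",
    "TML": "vehicles day-1 m",
    "HTL": "vehicles day-1 m",
    "IND": "m2",
    "HAR": "m2",
    "RES": "m2",
    "POP": "inhabitants",
}

#: Which road-class filter each traffic/road predictor uses, and for load
#: predictors which intensity attribute.
ROAD_PREDICTORS = {
    "RL": ("all", None),
    "MRL": ("major", None),
    "TL": ("all", "traffic_intensity"),
    "TML": ("major", "traffic_intensity"),
    "HTL": ("all", "heavy_traffic_intensity"),
}


@dataclass
class PredictorRaster:
    """An unbuffered per-cell predictor map."""

    raster: Raster
    predictor_id: str
    units: str

    def __post_init__(self) -> None:
        if self.predictor_id not in PREDICTOR_UNITS:
            raise ValueError(f"unknown predictor id {self.predictor_id!r}")
        expected = PREDICTOR_UNITS[self.predictor_id]
        if self.units != expected:
            raise ValueError(
                f"{self.predictor_id} must have units {expected!r}, "
                f"got {self.units!r}"
            )


# ------------------------------------------------------- line rasterization

def _segment_cell_lengths(spec: GridSpec, p0, p1):
    """Yield (row, col, clipped_length) for one straight edge.

    Parametric traversal: the edge is cut at every grid line it crosses;
    each piece is assigned to the cell containing its midpoint.  The piece
    lengths sum to the edge length inside the extent exactly (the parameter
    increments sum to the clipped parameter range).
    """
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    seg_len = math.hypot(dx, dy)
    if seg_len == 0.0:
        return
    # Liang-Barsky clip of parameter range to the grid extent
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - spec.x_min),
        (dx, spec.x_max - x0),
        (-dy, y0 - spec.y_min),
        (dy, spec.y_max - y0),
    ):
        if p == 0.0:
            if q < 0.0:
                return  # parallel and fully outside
            continue
        r = q / p
        if p < 0.0:
            if r > t1:
                return
            t0 = max(t0, r)
        else:
            if r < t0:
                return
            t1 = min(t1, r)
    if t0 >= t1:
        return

    cs = spec.cell_size
    ts = [t0, t1]
    if dx != 0.0:
        k_lo = math.ceil((min(x0 + t0 * dx, x0 + t1 * dx) - spec.x_min) / cs)
        k_hi = math.floor((max(x0 + t0 * dx, x0 + t1 * dx) - spec.x_min) / cs)
        for k in range(k_lo, k_hi + 1):
            ts.append((spec.x_min + k * cs - x0) / dx)
    if dy != 0.0:
        k_lo = math.ceil((min(y0 + t0 * dy, y0 + t1 * dy) - spec.y_min) / cs)
        k_hi = math.floor((max(y0 + t0 * dy, y0 + t1 * dy) - spec.y_min) / cs)
        for k in range(k_lo, k_hi + 1):
            ts.append((spec.y_min + k * cs - y0) / dy)
    ts = sorted(t for t in ts if t0 <= t <= t1)

    for ta, tb in zip(ts[:-1], ts[1:]):
        if tb <= ta:
            continue
        tm = 0.5 * (ta + tb)
        xm, ym = x0 + tm * dx, y0 + tm * dy
        col = int((xm - spec.x_min) // cs)
        row = int((spec.y_max - ym) // cs)
        if 0 <= row < spec.n_rows and 0 <= col < spec.n_cols:
            yield row, col, seg_len * (tb - ta)


def _accumulate_segments(spec: GridSpec, segments: list[RoadSegment],
                         weight_of) -> np.ndarray:
    out = np.zeros(spec.shape, dtype=np.float64)
    for seg in segments:
        w = weight_of(seg)
        for (a, b) in zip(seg.coords[:-1], seg.coords[1:]):
            for row, col, length in _segment_cell_lengths(spec, a, b):
                out[row, col] += length * w
    return out


def rasterize_line_length(roads: RoadNetwork, spec: GridSpec,
                          class_filter: str = "all") -> PredictorRaster:
    """Total clipped road length (m) per cell; RL for all roads, MRL for
    ``class_filter="major"``."""
    segments = roads.filtered(class_filter)
    values = _accumulate_segments(spec, segments, lambda s: 1.0)
    pid = "RL" if class_filter == "all" else "MRL"
    return PredictorRaster(Raster(spec, values), pid, PREDICTOR_UNITS[pid])


def rasterize_traffic_load(
    roads: RoadNetwork,
    spec: GridSpec,
    class_filter: str = "all",
    intensity_field: str = "traffic_intensity",
) -> PredictorRaster:
    """Traffic load per cell: sum over clipped segments of
    (clipped length x intensity), in vehicles day^-1 m.

    TL: all roads x traffic_intensity; TML: major roads x traffic_intensity;
    HTL: all roads x heavy_traffic_intensity.  A filtered segment without
    the intensity attribute is an error (missing is not zero).
    """
    segments = roads.filtered(class_filter)
    missing = [s.segment_id for s in segments
               if getattr(s, intensity_field) is None]
    if missing:
        raise ValueError(
            f"segments missing {intensity_field!r}: {missing} "
            "(missing intensity is not treated as zero)"
        )
    values = _accumulate_segments(
        spec, segments, lambda s: float(getattr(s, intensity_field))
    )
    if intensity_field == "heavy_traffic_intensity":
        pid = "HTL"
    else:
        pid = "TL" if class_filter == "all" else "TML"
    return PredictorRaster(Raster(spec, values), pid, PREDICTOR_UNITS[pid])


# ---------------------------------------------------- polygon rasterization

def _center_membership(spec: GridSpec, geometry) -> np.ndarray:
    """Boolean grid: does the cell centre lie on the geometry?

    Restricted to the geometry's bounding box for speed; boundary points
    count as inside (``intersects`` semantics).
    """
    xs, ys = spec.cell_centers()
    minx, miny, maxx, maxy = geometry.bounds
    ci = np.nonzero((xs >= minx) & (xs <= maxx))[0]
    ri = np.nonzero((ys >= miny) & (ys <= maxy))[0]
    out = np.zeros(spec.shape, dtype=bool)
    if ci.size == 0 or ri.size == 0:
        return out
    gx, gy = np.meshgrid(xs[ci], ys[ri])
    hit = shapely.intersects_xy(geometry, gx.ravel(), gy.ravel())
    out[np.ix_(ri, ci)] = hit.reshape(ri.size, ci.size)
    return out


def rasterize_class_area(landuse: LandUseLayer, spec: GridSpec,
                         target_class: str) -> PredictorRaster:
    """Class area per cell: cell_size^2 where the cell centre falls inside
    any polygon of the target class, else 0."""
    if target_class not in ("IND", "HAR", "RES"):
        raise ValueError(
            f"target class must be IND, HAR or RES, got {target_class!r}"
        )
    member = np.zeros(spec.shape, dtype=bool)
    for poly in landuse.polygons_of(target_class):
        member |= _center_membership(spec, poly.geometry)
    values = np.where(member, spec.cell_size ** 2, 0.0)
    return PredictorRaster(Raster(spec, values), target_class,
                           PREDICTOR_UNITS[target_class])


def rasterize_population(pop: PopulationLayer, spec: GridSpec) -> PredictorRaster:
    """Inhabitants per cell.

    A polygon zone's count is spread uniformly over the cells whose centres
    it covers; a point zone (or a sliver polygon covering no cell centre)
    puts all inhabitants in the single containing cell, so the total is
    conserved.  Zones wholly outside the grid are dropped.
    """
    values = np.zeros(spec.shape, dtype=np.float64)
    for zone in pop.zones:
        geom = zone.geometry
        if geom.geom_type == "Point":
            if spec.contains_point(geom.x, geom.y):
                r, c = spec.point_to_cell(geom.x, geom.y)
                values[r, c] += zone.inhabitants
            continue
        member = _center_membership(spec, geom)
        n = int(member.sum())
        if n > 0:
            values[member] += zone.inhabitants / n
        else:
            pt = geom.representative_point()
            if spec.contains_point(pt.x, pt.y):
                r, c = spec.point_to_cell(pt.x, pt.y)
                values[r, c] += zone.inhabitants
    return PredictorRaster(Raster(spec, values), "POP", PREDICTOR_UNITS["POP"])
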