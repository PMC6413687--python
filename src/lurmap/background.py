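"""Regional background surfaces by inverse-distance-weighted interpolation.

The LUR models take large-scale spatial trends from regional background
estimates — BEO (NO2), BEX (NOx), BEP (PM2.5) and BEA (PM2.5 absorbance) —
interpolated from dedicated regional monitoring stations with IDW inside a
search radius of 100 km.  PM10 has no background term: a regional estimate
did not improve that model, so requesting one is an error.

IDW with power p:  z(c) = sum_i d_i^-p v_i / sum_i d_i^-p  over stations
within the radius; a cell whose centre coincides with a station takes the
station value exactly; a cell with no station in range is NODATA.  The
exponent of the original maps is not published; 2 is the conventional
default and is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, Raster
from .vector import StationSet

__all__ = ["BackgroundRaster", "BACKGROUND_IDS", "idw_interpolate"]

#: pollutant -> background predictor id (PM10 deliberately absent)
BACKGROUND_IDS = {
    "NO2": "BEO",
    "NO2background": "BEO",
    "NOx": "BEX",
    "PM2.5": "BEP",
    "PM2.5absorbance": "BEA",
}

BACKGROUND_UNITS = {
    "BEO": "ug m-3",
    "BEX": "ug m-3",
    "BEP": "ug m-3",
    "BEA": "1e-5 m-1",
}


def background_id(pollutant: str) -> str:
    try:
        return BACKGROUND_IDS[pollutant]
    except KeyError:
        raise ValueError(
            f"no regional background estimate is defined for {pollutant!r} "
            "(PM10 has none by design)"
        ) from None


@dataclass
class BackgroundRaster:
    """An IDW-interpolated regional background surface (BEO/BEX/BEP/BEA)."""

    raster: Raster
    predictor_id: str
    units: str


def idw_interpolate(
    stations: StationSet,
    spec: GridSpec,
    radius: float = 100_000.0,
    power: float = 2.0,
    predictor_id: str = "BEO",
) -> BackgroundRaster:
    """Interpolate station values to the grid by inverse distance weighting.

    Values are convex combinations of the station values, so the surface
    lies within [min, max] of the contributing stations wherever defined.
    A station distance below cell_size/100 counts as coincident and the
    station value is taken exactly.
    """
    if len(stations) == 0:
        raise ValueError("IDW needs at least one station")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    if predictor_id not in BACKGROUND_UNITS:
        raise ValueError(f"unknown background predictor {predictor_id!r}")

    coords = stations.coordinates()
    vals = stations.values()
    xs, ys = spec.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    px = gx.ravel()
    py = gy.ravel()

    d = np.hypot(px[:, None] - coords[None, :, 0],
                 py[:, None] - coords[None, :, 1])
    snap = d < spec.cell_size / 100.0
    in_range = d <= radius

    with np.errstate(divide="ignore"):
        w = np.where(in_range, d ** (-power), 0.0)
    wsum = w.sum(axis=1)
    has_any = in_range.any(axis=1)

    out = np.full(px.shape, 0.0)
    ok = has_any & np.isfinite(wsum) & (wsum > 0)
    out[ok] = (w[ok] @ vals) / wsum[ok]

    # exact value at (near-)coincident cells, nearest station wins
    snap_rows = np.nonzero(snap.any(axis=1))[0]
    if snap_rows.size:
        nearest = np.argmin(d[snap_rows], axis=1)
        out[snap_rows] = vals[nearest]

    mask = ~has_any
    raster = Raster(spec, out.reshape(spec.shape), mask.reshape(spec.shape))
    return BackgroundRaster(raster, predictor_id, BACKGROUND_UNITS[predictor_id])
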