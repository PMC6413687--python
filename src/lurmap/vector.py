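"""Vector predictor inputs: road networks, land-use polygons, population
zones and monitoring stations.

GeoJSON is the single supported vector dialect and coordinates are assumed
to be in the working metric CRS already (no reprojection).  Stations come
from CSV with an ``id, x, y, value`` header.

A deliberate rule throughout: a *missing* traffic-intensity attribute is
recorded as absent, never silently treated as zero — traffic-load
predictors carry high weights in the LUR models and zero-filling would
bias them.
"""

from __future__ import annotations

import csv
import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, shape

__all__ = [
    "RoadSegment",
    "RoadNetwork",
    "LandUseLayer",
    "PopulationLayer",
    "Station",
    "StationSet",
    "read_roads",
    "read_landuse",
    "read_population",
    "read_stations",
    "read_reclass_table",
]

ROAD_CLASSES = ("all", "major")
LANDUSE_TARGETS = ("IND", "HAR", "RES", "other")


@dataclass
class RoadSegment:
    """One polyline road-lane centreline with optional traffic attributes.

    ``traffic_intensity`` and ``heavy_traffic_intensity`` are annual mean
    counts in vehicles per day; ``None`` means the attribute was not
    provided (distinct from zero traffic).
    """

    segment_id: str
    coords: list[tuple[float, float]]
    road_class: str = "all"
    traffic_intensity: float | None = None
    heavy_traffic_intensity: float | None = None

    def __post_init__(self) -> None:
        if len(self.coords) < 2:
            raise ValueError(f"segment {self.segment_id}: needs >= 2 vertices")
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(
                f"segment {self.segment_id}: unknown road class "
                f"{self.road_class!r} (expected one of {ROAD_CLASSES})"
            )
        for name in ("traffic_intensity", "heavy_traffic_intensity"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(
                    f"segment {self.segment_id}: {name} must be >= 0, got {v}"
                )

    @property
    def is_major(self) -> bool:
        return self.road_class == "major"

    def geometry(self) -> LineString:
        return LineString(self.coords)

    def length(self) -> float:
        c = np.asarray(self.coords)
        return float(np.sum(np.hypot(*np.diff(c, axis=0).T)))


@dataclass
class RoadNetwork:
    """All road-lane centrelines of a study area.

    Every "major" segment is also part of the "all" network — the class
    filter ``"all"`` therefore returns every segment.
    """

    segments: list[RoadSegment] = field(default_factory=list)

    def filtered(self, class_filter: str) -> list[RoadSegment]:
        if class_filter not in ROAD_CLASSES:
            raise ValueError(f"unknown road class filter {class_filter!r}")
        if class_filter == "all":
            return list(self.segments)
        return [s for s in self.segments if s.is_major]

    def total_length(self, class_filter: str = "all") -> float:
        return sum(s.length() for s in self.filtered(class_filter))


@dataclass
class LandUsePolygon:
    polygon_id: str
    geometry: object  # shapely Polygon / MultiPolygon
    source_class: str


@dataclass
class LandUseLayer:
    """Land-use polygons plus the reclassification of source classes into
    the LUR target classes industry (IND), harbour (HAR), residential (RES)
    and 'other'."""

    polygons: list[LandUsePolygon] = field(default_factory=list)
    reclass: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target in self.reclass.values():
            if target not in LANDUSE_TARGETS:
                raise ValueError(
                    f"reclass target {target!r} not in {LANDUSE_TARGETS}"
                )

    def target_class(self, source_class: str) -> str:
        try:
            return self.reclass[source_class]
        except KeyError:
            raise ValueError(
                f"land-use class {source_class!r} has no reclassification entry"
            ) from None

    def polygons_of(self, target_class: str) -> list[LandUsePolygon]:
        if target_class not in LANDUSE_TARGETS:
            raise ValueError(f"unknown land-use target class {target_class!r}")
        return [p for p in self.polygons
                if self.target_class(p.source_class) == target_class]


@dataclass
class PopulationZone:
    zone_id: str
    geometry: object  # shapely Polygon or Point
    inhabitants: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.inhabitants) or self.inhabitants < 0:
            raise ValueError(
                f"zone {self.zone_id}: inhabitants must be >= 0, "
                f"got {self.inhabitants}"
            )


@dataclass
class PopulationLayer:
    zones: list[PopulationZone] = field(default_factory=list)

    def total_population(self) -> float:
        return sum(z.inhabitants for z in self.zones)


SITE_TYPES = ("regional", "urban", "traffic", "industry")


@dataclass
class Station:
    station_id: str
    x: float
    y: float
    value: float
    site_type: str | None = None


@dataclass
class StationSet:
    """Point measurements: IDW-background inputs or validation sites."""

    stations: list[Station] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.station_id for s in self.stations]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate station ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.stations)

    def __iter__(self):
        return iter(self.stations)

    def coordinates(self) -> np.ndarray:
        return np.array([(s.x, s.y) for s in self.stations], dtype=np.float64)

    def values(self) -> np.ndarray:
        return np.array([s.value for s in self.stations], dtype=np.float64)


# ------------------------------------------------------------------ readers

def _load_geojson(path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def read_roads(
    path: str | os.PathLike,
    class_field: str = "road_class",
    intensity_field: str = "traffic_intensity",
    heavy_intensity_field: str = "heavy_traffic_intensity",
) -> RoadNetwork:
    """Read a road network from a GeoJSON file of LineString features.

    Raises with the offending feature ids on non-line geometries or
    unknown road-class values.
    """
    features = _load_geojson(path)
    segments = []
    bad_geom, bad_class = [], []
    for i, feat in enumerate(features):
        fid = str(feat.get("id", feat.get("properties", {}).get("id", i)))
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        if geom.get("type") != "LineString":
            bad_geom.append(fid)
            continue
        road_class = props.get(class_field, "all")
        if road_class not in ROAD_CLASSES:
            bad_class.append(fid)
            continue
        segments.append(
            RoadSegment(
                segment_id=fid,
                coords=[tuple(c) for c in geom["coordinates"]],
                road_class=road_class,
                traffic_intensity=props.get(intensity_field),
                heavy_traffic_intensity=props.get(heavy_intensity_field),
            )
        )
    if bad_geom:
        raise ValueError(f"{path}: non-LineString geometries at features {bad_geom}")
    if bad_class:
        raise ValueError(f"{path}: unknown road class values at features {bad_class}")
    return RoadNetwork(segments)


def read_landuse(path: str | os.PathLike, reclass: dict[str, str],
                 class_field: str = "landuse") -> LandUseLayer:
    """Read land-use polygons from GeoJSON and attach a reclass table.

    Invalid polygons are repaired with shapely's ``make_valid``-style
    zero-buffer; every present source class must appear in the table.
    """
    features = _load_geojson(path)
    polys = []
    for i, feat in enumerate(features):
        fid = str(feat.get("id", feat.get("properties", {}).get("id", i)))
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        if geom.get("type") not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"{path}: feature {fid} is not a polygon")
        g = shape(geom)
        if not g.is_valid:
            g = g.buffer(0)
        source = props.get(class_field)
        if source is None:
            raise ValueError(f"{path}: feature {fid} lacks {class_field!r}")
        polys.append(LandUsePolygon(fid, g, str(source)))
    layer = LandUseLayer(polys, dict(reclass))
    for p in layer.polygons:
        layer.target_class(p.source_class)  # fail early on unmapped classes
    return layer


def read_population(path: str | os.PathLike,
                    count_field: str = "inhabitants") -> PopulationLayer:
    features = _load_geojson(path)
    zones = []
    for i, feat in enumerate(features):
        fid = str(feat.get("id", feat.get("properties", {}).get("id", i)))
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        if geom.get("type") not in ("Polygon", "MultiPolygon", "Point"):
            raise ValueError(
                f"{path}: feature {fid} must be Polygon or Point"
            )
        count = props.get(count_field)
        if count is None:
            raise ValueError(f"{path}: feature {fid} lacks {count_field!r}")
        zones.append(PopulationZone(fid, shape(geom), float(count)))
    return PopulationLayer(zones)


def read_reclass_table(path: str | os.PathLike) -> dict[str, str]:
    """Two-column CSV (source_class, target_class) -> dict."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["source_class", "target_class"]:
            raise ValueError(f"{path}: expected header source_class,target_class")
        for row in reader:
            if not row:
                continue
            src, tgt = row[0].strip(), row[1].strip()
            if src in out and out[src] != tgt:
                raise ValueError(f"{path}: class {src!r} mapped twice")
            out[src] = tgt
    return out


def read_stations(path: str | os.PathLike) -> StationSet:
    """Read stations from CSV with columns id, x, y, value[, site_type].

    Rows with a missing value are rejected and counted in the error; a
    duplicate id is an error naming the id (via StationSet validation).
    """
    stations = []
    n_missing = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "x", "y", "value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: station CSV must have columns {sorted(required)}"
            )
        for row in reader:
            raw = (row.get("value") or "").strip()
            if raw == "" or raw.upper() in ("NA", "NAN"):
                n_missing += 1
                continue
            stations.append(
                Station(
                    station_id=row["id"].strip(),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    value=float(raw),
                    site_type=(row.get("site_type") or "").strip() or None,
                )
            )
    if n_missing:
        warnings.warn(
            f"{path}: dropped {n_missing} station rows with missing values",
            stacklevel=2,
        )
    return StationSet(stations)
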