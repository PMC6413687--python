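"""Seeded synthetic study area: a toy town exercising the whole pipeline.

Real national inputs (commercial road networks with traffic counts,
CORINE land cover, population registers) cannot be redistributed, so this
module generates a structurally similar scene: a major-road ring with
crossing arterials carrying heavy traffic, a minor street grid, blocky
industrial/harbour/residential land use, population spread over the
residential blocks, regional background stations with a smooth large-scale
concentration field, and validation sites.

All geometry is axis-aligned and lattice-like on purpose: rectangle areas
and straight-line lengths have closed forms, which makes the scene usable
as an analytic oracle in tests.  Everything is a pure function of the
seed; writing the scene twice produces byte-identical files.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, mapping

from .grid import GridSpec
from .models import LURModel, evaluate
from .vector import (
    LandUseLayer,
    LandUsePolygon,
    PopulationLayer,
    PopulationZone,
    RoadNetwork,
    RoadSegment,
    Station,
    StationSet,
)

__all__ = ["SceneConfig", "Scene", "generate_scene", "scene_predictor_stack",
           "forward_observations", "write_scene"]

#: plausible regional background levels for the four interpolated surfaces
_BACKGROUND_LEVELS = {
    "BEO": 20.0,   # NO2, ug m-3
    "BEX": 30.0,   # NOx, ug m-3
    "BEP": 15.0,   # PM2.5, ug m-3
    "BEA": 1.2,    # PM2.5 absorbance, 1e-5 m-1
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic study area.

    Defaults: a 2 km x 2 km domain at 5 m cells (400 x 400), a ring road
    plus four arterials with 10k-40k vehicles/day, a 16-street minor grid
    with 0.5k-5k vehicles/day, 10% heavy traffic, a handful of land-use
    blocks, 50 000 inhabitants, 10 regional background stations (the PM
    networks of this size are the small case; pass 20 for an NOx-sized
    network) and 200 validation sites with 2 ug m^-3 measurement noise.
    """

    seed: int = 0
    x_min: float = 0.0
    y_max: float = 2000.0
    cell_size: float = 5.0
    n_rows: int = 400
    n_cols: int = 400
    n_major_roads: int = 4
    n_minor_roads: int = 16
    major_intensity: tuple[float, float] = (10_000.0, 40_000.0)
    minor_intensity: tuple[float, float] = (500.0, 5_000.0)
    heavy_fraction: float = 0.10
    n_industry_blocks: int = 2
    n_harbour_blocks: int = 1
    n_residential_blocks: int = 6
    total_population: float = 50_000.0
    n_background_stations: int = 10
    n_validation_sites: int = 200
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("scene extent is degenerate (need >= 10x10 cells)")
        for name in ("n_major_roads", "n_minor_roads", "n_industry_blocks",
                     "n_harbour_blocks", "n_residential_blocks",
                     "n_background_stations", "n_validation_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_population < 0 or self.noise_sd < 0:
            raise ValueError("population and noise_sd must be >= 0")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.x_min, self.y_max, self.cell_size,
                        self.n_rows, self.n_cols)


@dataclass
class Scene:
    config: SceneConfig
    spec: GridSpec
    roads: RoadNetwork
    landuse: LandUseLayer
    population: PopulationLayer
    background_stations: dict[str, StationSet]
    validation_sites: np.ndarray = field(default=None)  # (n, 2)


def _jittered_positions(rng, n: int, lo: float, hi: float) -> np.ndarray:
    """n distinct positions in (lo, hi), roughly evenly spread."""
    edges = np.linspace(lo, hi, n + 1)
    pos = edges[:-1] + (edges[1:] - edges[:-1]) * rng.uniform(0.15, 0.85, n)
    return pos


def _make_roads(cfg: SceneConfig, rng) -> RoadNetwork:
    spec = cfg.spec
    x0, x1 = spec.x_min, spec.x_max
    y0, y1 = spec.y_min, spec.y_max
    w, h = x1 - x0, y1 - y0
    segments: list[RoadSegment] = []

    def major(sid, coords):
        inten = float(rng.uniform(*cfg.major_intensity))
        segments.append(RoadSegment(
            sid, coords, "major",
            traffic_intensity=inten,
            heavy_traffic_intensity=inten * cfg.heavy_fraction,
        ))

    # ring road at 15% inset, one closed polyline
    rx0, rx1 = x0 + 0.15 * w, x1 - 0.15 * w
    ry0, ry1 = y0 + 0.15 * h, y1 - 0.15 * h
    major("ring", [(rx0, ry0), (rx1, ry0), (rx1, ry1), (rx0, ry1), (rx0, ry0)])

    # crossing arterials, alternating vertical/horizontal
    n_v = (cfg.n_major_roads + 1) // 2
    n_h = cfg.n_major_roads // 2
    for i, x in enumerate(_jittered_positions(rng, n_v, x0 + 0.2 * w, x1 - 0.2 * w)):
        major(f"arterial_v{i}", [(float(x), y0), (float(x), y1)])
    for i, y in enumerate(_jittered_positions(rng, n_h, y0 + 0.2 * h, y1 - 0.2 * h)):
        major(f"arterial_h{i}", [(x0, float(y)), (x1, float(y))])

    # minor street grid
    n_v = (cfg.n_minor_roads + 1) // 2
    n_h = cfg.n_minor_roads // 2
    for i, x in enumerate(_jittered_positions(rng, n_v, x0 + 0.05 * w, x1 - 0.05 * w)):
        inten = float(rng.uniform(*cfg.minor_intensity))
        segments.append(RoadSegment(
            f"street_v{i}", [(float(x), y0), (float(x), y1)], "all",
            traffic_intensity=inten,
            heavy_traffic_intensity=inten * cfg.heavy_fraction,
        ))
    for i, y in enumerate(_jittered_positions(rng, n_h, y0 + 0.05 * h, y1 - 0.05 * h)):
        inten = float(rng.uniform(*cfg.minor_intensity))
        segments.append(RoadSegment(
            f"street_h{i}", [(x0, float(y)), (x1, float(y))], "all",
            traffic_intensity=inten,
            heavy_traffic_intensity=inten * cfg.heavy_fraction,
        ))
    return RoadNetwork(segments)


def _random_block(rng, spec: GridSpec, min_size: float, max_size: float) -> Polygon:
    w = float(rng.uniform(min_size, max_size))
    h = float(rng.uniform(min_size, max_size))
    bx = float(rng.uniform(spec.x_min, spec.x_max - w))
    by = float(rng.uniform(spec.y_min, spec.y_max - h))
    return Polygon([(bx, by), (bx + w, by), (bx + w, by + h), (bx, by + h)])


def _make_landuse(cfg: SceneConfig, rng) -> LandUseLayer:
    spec = cfg.spec
    polys = []
    counts = (
        ("industry", cfg.n_industry_blocks, (150.0, 400.0)),
        ("harbour", cfg.n_harbour_blocks, (150.0, 350.0)),
        ("residential", cfg.n_residential_blocks, (200.0, 500.0)),
    )
    i = 0
    for source, n, size in counts:
        for _ in range(n):
            polys.append(LandUsePolygon(
                f"lu{i}", _random_block(rng, spec, *size), source))
            i += 1
    reclass = {"industry": "IND", "harbour": "HAR",
               "residential": "RES", "agriculture": "other"}
    return LandUseLayer(polys, reclass)


def _make_population(cfg: SceneConfig, landuse: LandUseLayer, rng) -> PopulationLayer:
    res = landuse.polygons_of("RES")
    zones = []
    if not res:
        spec = cfg.spec
        centre = _random_block(rng, spec, 300.0, 600.0)
        zones.append(PopulationZone("pop0", centre, cfg.total_population))
        return PopulationLayer(zones)
    areas = np.array([p.geometry.area for p in res])
    shares = areas / areas.sum()
    for i, (poly, share) in enumerate(zip(res, shares)):
        zones.append(PopulationZone(
            f"pop{i}", poly.geometry, float(cfg.total_population * share)))
    return PopulationLayer(zones)


def _make_background_stations(cfg: SceneConfig, rng) -> dict[str, StationSet]:
    """Regional stations with a smooth large-scale field per pollutant:
    a base level, a linear trend across the domain and a little
    station-to-station scatter."""
    spec = cfg.spec
    n = cfg.n_background_stations
    xs = rng.uniform(spec.x_min, spec.x_max, n)
    ys = rng.uniform(spec.y_min, spec.y_max, n)
    out = {}
    for pid, level in _BACKGROUND_LEVELS.items():
        gx, gy = rng.uniform(-0.15, 0.15, 2)
        scatter = rng.normal(0.0, 0.03 * level, n)
        vals = level * (
            1.0
            + gx * (xs - spec.x_min) / (spec.x_max - spec.x_min)
            + gy * (ys - spec.y_min) / (spec.y_max - spec.y_min)
        ) + scatter
        vals = np.maximum(vals, 0.05 * level)
        out[pid] = StationSet([
            Station(f"{pid.lower()}{i}", float(xs[i]), float(ys[i]),
                    float(vals[i]), "regional")
            for i in range(n)
        ])
    return out


def generate_scene(config: SceneConfig | None = None) -> Scene:
    """Build the full synthetic scene from the seed."""
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    roads = _make_roads(cfg, rng)
    landuse = _make_landuse(cfg, rng)
    population = _make_population(cfg, landuse, rng)
    stations = _make_background_stations(cfg, rng)
    spec = cfg.spec
    margin = 2 * cfg.cell_size
    sites = np.column_stack([
        rng.uniform(spec.x_min + margin, spec.x_max - margin,
                    cfg.n_validation_sites),
        rng.uniform(spec.y_min + margin, spec.y_max - margin,
                    cfg.n_validation_sites),
    ])
    return Scene(cfg, spec, roads, landuse, population, stations, sites)


def scene_predictor_stack(scene: Scene, tile_rows: int | None = None,
                          d_min: float = 2.5, idw_radius: float = 100_000.0,
                          idw_power: float = 2.0) -> dict:
    """Compute, in memory, every predictor surface the six built-in models
    need from a scene: rasterized bases, buffered sums, inverse distances
    and IDW backgrounds, keyed by term name ('POP_5000', 'IDC', 'BEO', ...).

    The file-writing equivalent is :func:`lurmap.pipeline.run_pipeline`.
    """
    from .background import idw_interpolate
    from .buffers import compute_predictor_stack
    from .distances import distance_to_network, inverse_distance
    from .models import builtin_models, required_buffered_terms
    from .rasterize import (
        ROAD_PREDICTORS,
        rasterize_class_area,
        rasterize_line_length,
        rasterize_population,
        rasterize_traffic_load,
    )

    spec = scene.spec
    base = {}
    for pid, (class_filter, intensity) in ROAD_PREDICTORS.items():
        if intensity is None:
            base[pid] = rasterize_line_length(scene.roads, spec, class_filter)
        else:
            base[pid] = rasterize_traffic_load(scene.roads, spec,
                                               class_filter, intensity)
    for pid in ("IND", "HAR", "RES"):
        base[pid] = rasterize_class_area(scene.landuse, spec, pid)
    base["POP"] = rasterize_population(scene.population, spec)

    terms = required_buffered_terms(builtin_models())
    stack = {key: bp.raster for key, bp in
             compute_predictor_stack(base, terms, tile_rows=tile_rows).items()}
    for pid, class_filter in (("IDC", "all"), ("IDM", "major")):
        dist = distance_to_network(scene.roads, spec, class_filter)
        stack[pid] = inverse_distance(dist, d_min).raster
    for pid, stations in scene.background_stations.items():
        stack[pid] = idw_interpolate(stations, spec, radius=idw_radius,
                                     power=idw_power, predictor_id=pid).raster
    return stack


def forward_observations(model: LURModel, stack: dict, sites: np.ndarray,
                         noise_sd: float, seed: int) -> StationSet:
    """Synthetic observations: the model surface at each site plus seeded
    Gaussian noise.  With noise_sd = 0 validating the model against these
    observations is an exact identity (r^2 = 1, RMSE = bias = 0)."""
    surface = evaluate(model, stack)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, len(sites)) if noise_sd > 0 \
        else np.zeros(len(sites))
    stations = []
    for i, (x, y) in enumerate(sites):
        value = surface.value_at(float(x), float(y))
        stations.append(Station(f"site{i}", float(x), float(y),
                                float(value + noise[i])))
    return StationSet(stations)


# ------------------------------------------------------------- fixtures IO

def _write_geojson(path, features) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_stations_csv(stations: StationSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "value", "site_type"])
        for s in stations:
            writer.writerow([s.station_id, repr(s.x), repr(s.y),
                             repr(s.value), s.site_type or ""])


def write_scene(scene: Scene, directory) -> dict[str, str]:
    """Materialise the scene as the GeoJSON/CSV dialects the readers
    consume; returns a manifest of written paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {}

    features = []
    for seg in scene.roads.segments:
        features.append({
            "type": "Feature",
            "id": seg.segment_id,
            "geometry": {"type": "LineString",
                         "coordinates": [list(c) for c in seg.coords]},
            "properties": {
                "road_class": seg.road_class,
                "traffic_intensity": seg.traffic_intensity,
                "heavy_traffic_intensity": seg.heavy_traffic_intensity,
            },
        })
    paths["roads"] = os.path.join(directory, "roads.geojson")
    _write_geojson(paths["roads"], features)

    features = [{
        "type": "Feature",
        "id": p.polygon_id,
        "geometry": mapping(p.geometry),
        "properties": {"landuse": p.source_class},
    } for p in scene.landuse.polygons]
    paths["landuse"] = os.path.join(directory, "landuse.geojson")
    _write_geojson(paths["landuse"], features)

    features = [{
        "type": "Feature",
        "id": z.zone_id,
        "geometry": mapping(z.geometry),
        "properties": {"inhabitants": z.inhabitants},
    } for z in scene.population.zones]
    paths["population"] = os.path.join(directory, "population.geojson")
    _write_geojson(paths["population"], features)

    paths["reclass"] = os.path.join(directory, "reclass.csv")
    with open(paths["reclass"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_class", "target_class"])
        for src in sorted(scene.landuse.reclass):
            writer.writerow([src, scene.landuse.reclass[src]])

    for pid, stations in scene.background_stations.items():
        key = f"stations_{pid}"
        paths[key] = os.path.join(directory, f"{key}.csv")
        write_stations_csv(stations, paths[key])

    if scene.validation_sites is not None:
        paths["sites"] = os.path.join(directory, "validation_sites.csv")
        with open(paths["sites"], "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y"])
            for i, (x, y) in enumerate(scene.validation_sites):
                writer.writerow([f"site{i}", repr(float(x)), repr(float(y))])
    return paths
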