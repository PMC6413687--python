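"""Vector-to-raster conversion: lengths, loads, class areas, population."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from lurmap.grid import GridSpec
from lurmap.rasterize import (
    rasterize_class_area,
    rasterize_line_length,
    rasterize_population,
    rasterize_traffic_load,
)
from lurmap.vector import (
    LandUseLayer,
    LandUsePolygon,
    PopulationLayer,
    PopulationZone,
    RoadNetwork,
    RoadSegment,
)
from .oracles import dense_sample_lengths


@pytest.fixture
def spec():
    return GridSpec(0.0, 50.0, 5.0, 10, 10)


def _net(*segments):
    return RoadNetwork(list(segments))


class TestLineLength:
    def test_segment_spanning_one_cell(self, spec):
        net = _net(RoadSegment("s", [(0.0, 2.5), (5.0, 2.5)]))
        out = rasterize_line_length(net, spec)
        assert out.raster.values[9, 0] == pytest.approx(5.0)
        assert out.raster.values.sum() == pytest.approx(5.0)

    def test_cell_diagonal(self, spec):
        net = _net(RoadSegment("d", [(0.0, 50.0), (5.0, 45.0)]))
        out = rasterize_line_length(net, spec)
        assert out.raster.values[0, 0] == pytest.approx(5 * math.sqrt(2))

    def test_conservation_random_networks(self, spec):
        """Per-cell lengths sum to the clipped network total, and match a
        1 mm dense-sampling oracle within 0.1% per cell."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            coords = [tuple(rng.uniform(2, 48, 2)) for _ in range(4)]
            net = _net(RoadSegment("w", coords))
            out = rasterize_line_length(net, spec).raster.values
            total = sum(
                math.dist(a, b) for a, b in zip(coords[:-1], coords[1:])
            )
            assert out.sum() == pytest.approx(total, rel=1e-9)
            oracle = dense_sample_lengths(spec, coords)
            np.testing.assert_allclose(out, oracle, atol=2e-3,
                                       rtol=1e-3)

    def test_segment_partly_outside_clipped(self, spec):
        net = _net(RoadSegment("s", [(-10.0, 2.5), (5.0, 2.5)]))
        out = rasterize_line_length(net, spec)
        assert out.raster.values.sum() == pytest.approx(5.0)

    def test_major_filter(self, spec):
        net = _net(
            RoadSegment("maj", [(0.0, 2.5), (10.0, 2.5)], "major"),
            RoadSegment("min", [(0.0, 12.5), (10.0, 12.5)], "all"),
        )
        mrl = rasterize_line_length(net, spec, "major")
        assert mrl.predictor_id == "MRL"
        assert mrl.raster.values.sum() == pytest.approx(10.0)


class TestTrafficLoad:
    def test_length_times_intensity(self, spec):
        net = _net(RoadSegment("s", [(0.0, 2.5), (5.0, 2.5)],
                               traffic_intensity=1000.0))
        out = rasterize_traffic_load(net, spec)
        assert out.raster.values[9, 0] == pytest.approx(5000.0)

    def test_zero_intensity_zero_raster(self, spec):
        net = _net(RoadSegment("s", [(0.0, 2.5), (45.0, 42.5)],
                               traffic_intensity=0.0))
        out = rasterize_traffic_load(net, spec)
        assert not out.raster.values.any()

    def test_missing_intensity_names_segment(self, spec):
        net = _net(RoadSegment("anon", [(0.0, 2.5), (5.0, 2.5)]))
        with pytest.raises(ValueError, match="anon"):
            rasterize_traffic_load(net, spec)

    def test_decomposition_by_intensity(self, spec):
        """Traffic load equals the per-intensity length rasters scaled and
        summed — load is linear in intensity."""
        rng = np.random.default_rng(5)
        segs = [
            RoadSegment(f"s{i}", [tuple(rng.uniform(0, 50, 2)),
                                  tuple(rng.uniform(0, 50, 2))],
                        traffic_intensity=float(rng.choice([100, 2000, 35000])))
            for i in range(8)
        ]
        tl = rasterize_traffic_load(_net(*segs), spec).raster.values
        expect = np.zeros(spec.shape)
        for s in segs:
            rl = rasterize_line_length(_net(s), spec).raster.values
            expect += rl * s.traffic_intensity
        np.testing.assert_allclose(tl, expect, rtol=1e-12, atol=1e-9)

    def test_doubling_intensity_doubles_load(self, spec):
        seg = RoadSegment("s", [(1.0, 1.0), (44.0, 47.0)],
                          traffic_intensity=1500.0)
        seg2 = RoadSegment("s", [(1.0, 1.0), (44.0, 47.0)],
                           traffic_intensity=3000.0)
        a = rasterize_traffic_load(_net(seg), spec).raster.values
        b = rasterize_traffic_load(_net(seg2), spec).raster.values
        np.testing.assert_array_equal(b, 2.0 * a)


class TestClassArea:
    def _layer(self, *polys):
        return LandUseLayer(
            [LandUsePolygon(f"p{i}", g, src) for i, (g, src) in enumerate(polys)],
            {"industry": "IND", "harbour": "HAR", "residential": "RES"},
        )

    def test_full_cover_gives_25_everywhere(self, spec):
        layer = self._layer((box(-1, -1, 51, 51), "industry"))
        out = rasterize_class_area(layer, spec, "IND")
        np.testing.assert_array_equal(out.raster.values, 25.0)

    def test_empty_class_zero_raster(self, spec):
        layer = self._layer((box(0, 0, 50, 50), "industry"))
        out = rasterize_class_area(layer, spec, "RES")
        assert not out.raster.values.any()

    def test_values_binary(self, spec):
        layer = self._layer((box(3, 3, 27, 34), "residential"))
        out = rasterize_class_area(layer, spec, "RES")
        assert set(np.unique(out.raster.values)) <= {0.0, 25.0}

    def test_area_matches_rectangles(self, spec):
        """Summed cell areas approximate the true rectangle area within a
        one-cell band around the perimeter."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            x0, y0 = rng.uniform(0, 25, 2)
            w, h = rng.uniform(5, 24, 2)
            rect = box(x0, y0, x0 + w, y0 + h)
            layer = self._layer((rect, "industry"))
            out = rasterize_class_area(layer, spec, "IND")
            tol = 2 * (w + h) * spec.cell_size + 4 * spec.cell_size ** 2
            assert abs(out.raster.values.sum() - rect.area) <= tol


class TestPopulation:
    def test_uniform_spread(self, spec):
        # 10x10-cell polygon = 100 covered centres, 1000 inhabitants
        layer = PopulationLayer([PopulationZone("z", box(0, 0, 50, 50), 1000.0)])
        out = rasterize_population(layer, spec)
        np.testing.assert_allclose(out.raster.values, 10.0)

    def test_point_source_single_cell(self, spec):
        layer = PopulationLayer([PopulationZone("z", Point(12.0, 33.0), 250.0)])
        out = rasterize_population(layer, spec)
        r, c = spec.point_to_cell(12.0, 33.0)
        assert out.raster.values[r, c] == 250.0
        assert out.raster.values.sum() == 250.0

    def test_disjoint_polygons_conserve_each(self, spec):
        layer = PopulationLayer([
            PopulationZone("a", box(0, 30, 20, 50), 600.0),
            PopulationZone("b", box(30, 0, 50, 20), 400.0),
        ])
        out = rasterize_population(layer, spec).raster.values
        assert out[:4, :4].sum() == pytest.approx(600.0)
        assert out[6:, 6:].sum() == pytest.approx(400.0)
        assert out.sum() == pytest.approx(1000.0)

    def test_sliver_polygon_conserves_total(self, spec):
        # too thin to cover any cell centre: falls back to one cell
        sliver = Polygon([(11, 11), (11.4, 11), (11.4, 11.4), (11, 11.4)])
        layer = PopulationLayer([PopulationZone("s", sliver, 42.0)])
        out = rasterize_population(layer, spec)
        assert out.raster.values.sum() == pytest.approx(42.0)
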