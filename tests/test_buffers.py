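"""Focal buffer engine: kernels, focal and annulus sums, predictor stacks."""

import numpy as np
import pytest

from lurmap.buffers import (
    annulus_sum,
    buffer_key,
    compute_predictor_stack,
    focal_sum,
    make_annulus_kernel,
    make_kernel,
)
from lurmap.buffers import _focal_values  # tiling path, tested directly
from lurmap.grid import GridSpec, Raster
from lurmap.models import builtin_model, builtin_models, required_buffered_terms
from .conftest import random_raster
from .oracles import annulus_offsets, brute_force_focal, disk_offsets


class TestKernel:
    @pytest.mark.parametrize("radius,expected_cells", [
        (2.4, 1),    # all neighbours at >= 5 m
        (5.0, 5),    # centre + 4-neighbourhood
        (25.0, 81),  # the classic disk: integer pairs with i^2+j^2 <= 25
    ])
    def test_cell_counts(self, radius, expected_cells):
        kernel = make_kernel(radius, 5.0)
        assert kernel.n_cells == expected_cells

    def test_matches_independent_enumeration(self):
        for radius in (10.0, 25.0, 60.0, 125.0, 303.0):
            kernel = make_kernel(radius, 5.0)
            assert kernel.offsets() == sorted(disk_offsets(radius, 5.0))

    def test_contains_centre_and_symmetry(self):
        kernel = make_kernel(60.0, 5.0)
        offsets = set(kernel.offsets())
        assert (0, 0) in offsets
        for (i, j) in offsets:
            for sym in [(-i, j), (i, -j), (j, i), (-j, -i)]:
                assert sym in offsets

    def test_boundary_ties_included(self):
        # the 3-4-5 triangle lies exactly on the 25 m circle at 5 m cells
        assert (3, 4) in set(make_kernel(25.0, 5.0).offsets())

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            make_kernel(-1.0, 5.0)

    def test_annulus_kernel_is_set_difference(self):
        kernel = make_annulus_kernel(25.0, 125.0, 5.0)
        assert kernel.offsets() == sorted(annulus_offsets(25.0, 125.0, 5.0))

    def test_annulus_needs_ordered_radii(self):
        with pytest.raises(ValueError):
            make_annulus_kernel(100.0, 50.0, 5.0)


class TestFocalSum:
    def test_radius_zero_is_identity(self):
        r = random_raster(np.random.default_rng(0))
        out = focal_sum(r, 0.0)
        np.testing.assert_array_equal(out.values, r.values)

    def test_constant_interior_value(self):
        spec = GridSpec(0, 250, 5.0, 50, 50)
        out = focal_sum(Raster.full(spec, 3.0), 25.0)
        # interior cells see the full 81-cell kernel
        assert out.values[25, 25] == 81 * 3.0
        # border cells see less (zero padding)
        assert out.values[0, 0] < 81 * 3.0

    @pytest.mark.parametrize("radius", [10.0, 25.0, 60.0, 125.0])
    def test_matches_brute_force_exactly(self, radius):
        """Bitwise equality with a sequential per-cell double loop on
        random rasters — the central engine contract."""
        rng = np.random.default_rng(42)
        offsets = sorted(disk_offsets(radius, 5.0))
        for _ in range(30):
            r = random_raster(rng)
            out = focal_sum(r, radius)
            expected = brute_force_focal(r.values, offsets)
            np.testing.assert_array_equal(out.values, expected)

    @pytest.mark.parametrize("r_inner,r_outer", [(10.0, 25.0), (25.0, 125.0)])
    def test_annulus_matches_brute_force_exactly(self, r_inner, r_outer):
        rng = np.random.default_rng(43)
        offsets = sorted(annulus_offsets(r_inner, r_outer, 5.0))
        for _ in range(10):
            r = random_raster(rng)
            out = annulus_sum(r, r_inner, r_outer)
            np.testing.assert_array_equal(
                out.values, brute_force_focal(r.values, offsets))

    def test_large_kernel_path_matches_brute_force(self):
        """The sliding-window path (kernels above the exact-path size
        threshold) agrees with brute force to float accumulation error."""
        rng = np.random.default_rng(44)
        r = random_raster(rng, 40, 40)
        radius = 600.0  # 120-cell radius -> ~45k offsets -> sliding path
        out = focal_sum(r, radius)
        expected = brute_force_focal(r.values, sorted(disk_offsets(radius, 5.0)))
        np.testing.assert_allclose(out.values, expected, rtol=1e-10)

    def test_annulus_constant_uses_ring_counts(self):
        spec = GridSpec(0, 1250, 5.0, 250, 250)
        v = 2.5
        out = annulus_sum(Raster.full(spec, v), 25.0, 500.0)
        n_ring = (make_kernel(500.0, 5.0).n_cells
                  - make_kernel(25.0, 5.0).n_cells)
        assert out.values[125, 125] == pytest.approx(n_ring * v)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(1)
        r = random_raster(rng)
        r.values[:] = np.abs(r.values)
        prev = focal_sum(r, 10.0).values
        for radius in (25.0, 60.0, 125.0):
            cur = focal_sum(r, radius).values
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x = random_raster(rng)
        y = Raster(x.spec, rng.normal(size=x.spec.shape))
        lhs = focal_sum(Raster(x.spec, 2.0 * x.values + 3.0 * y.values), 25.0)
        rhs = 2.0 * focal_sum(x, 25.0).values + 3.0 * focal_sum(y, 25.0).values
        np.testing.assert_allclose(lhs.values, rhs, rtol=1e-12)

    def test_border_underestimation_for_constants(self):
        spec = GridSpec(0, 250, 5.0, 50, 50)
        out = focal_sum(Raster.full(spec, 1.0), 60.0).values
        interior = out[25, 25]
        assert (out <= interior + 1e-12).all()
        assert out[0, 0] < interior

    def test_nodata_contributes_zero_but_tracked(self):
        spec = GridSpec(0, 50, 5.0, 10, 10)
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        r = Raster(spec, np.ones((10, 10)), mask)
        out = focal_sum(r, 5.0)
        # neighbour of the NODATA cell: one contribution lost
        assert out.values[5, 6] == 4.0
        assert not out.mask[5, 6]

    def test_all_nodata_neighbourhood_is_nodata(self):
        spec = GridSpec(0, 50, 5.0, 10, 10)
        mask = np.ones((10, 10), dtype=bool)
        r = Raster(spec, np.ones((10, 10)), mask)
        out = focal_sum(r, 25.0)
        assert out.mask.all()


@pytest.mark.parametrize("radius", [60.0, 600.0])  # one per engine path
def test_tiled_bands_bit_identical(radius):
    rng = np.random.default_rng(9)
    r = random_raster(rng, 60, 45)
    kernel = make_kernel(radius, 5.0)
    untiled = _focal_values(r.values, kernel, None)
    for tile_rows in (1, 7, 64):
        tiled = _focal_values(r.values, kernel, tile_rows)
        np.testing.assert_array_equal(tiled, untiled)


class TestPredictorStack:
    def test_all_six_models_need_16_predictors(self):
        terms = required_buffered_terms(builtin_models())
        assert len(terms) == 16

    def test_pm10_only_three_predictors(self):
        terms = required_buffered_terms([builtin_model("PM10")])
        assert sorted(buffer_key(p, b) for p, b in terms) == \
            ["MRL_50", "POP_5000", "TML_500"]

    def test_empty_request_empty_stack(self):
        assert compute_predictor_stack({}, []) == {}

    def test_missing_base_raster_names_predictor(self):
        with pytest.raises(ValueError, match="POP"):
            compute_predictor_stack({}, [("POP", 1000.0)])

    def test_deduplication(self):
        spec = GridSpec(0, 50, 5.0, 10, 10)
        base = {"POP": Raster.full(spec, 1.0)}
        stack = compute_predictor_stack(
            base, [("POP", 1000.0), ("POP", 1000.0)])
        assert list(stack) == ["POP_1000"]
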