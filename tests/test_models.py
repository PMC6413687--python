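"""The LUR model registry and per-cell / per-point evaluation."""

import numpy as np
import pytest

from lurmap.grid import GridSpec, Raster
from lurmap.models import (
    LURTerm,
    builtin_model,
    builtin_models,
    derive_pm_coarse,
    evaluate,
    evaluate_at_points,
    evaluation_summary,
    model_from_dict,
    model_to_dict,
)

SPEC = GridSpec(0.0, 50.0, 5.0, 10, 10)

#: every published coefficient, pinned (pollutant -> intercept, {key: coef})
PINNED = {
    "NO2": (-7.8, {"BEO": 1.18, "POP_5000": 2.3e-05, "TL_50": 2.47e-06,
                   "RL_1000": 1.06e-4, "HTL_25": 9.84e-05, "IDC": 12.19,
                   "HTL_25-500": 4.47e-07}),
    "NO2background": (3.21, {"BEO": 0.74, "POP_5000": 2.29e-05,
                             "IND_5000": 6.4e-07, "HAR_5000": 4.72e-07}),
    "NOx": (3.25, {"BEX": 0.74, "TL_50": 4.22e-06, "POP_1000": 6.36e-04,
                   "HTL_500": 2.39e-06, "IDM": 71.65, "MRL_25": 0.21}),
    "PM2.5": (9.46, {"BEP": 0.42, "MRL_50": 0.014, "TML_1000": 2.28e-09}),
    "PM2.5absorbance": (0.07, {"TL_500": 2.95e-09, "MRL_50": 0.0029,
                               "BEA": 0.85, "RES_5000": 7.90e-09,
                               "HTL_50": 1.72e-06}),
    "PM10": (23.71, {"TML_500": 2.16e-08, "POP_5000": 6.68e-06,
                     "MRL_50": 0.015}),
}


class TestRegistry:
    def test_six_models(self):
        assert len(builtin_models()) == 6
        assert {m.pollutant for m in builtin_models()} == set(PINNED)

    @pytest.mark.parametrize("pollutant", sorted(PINNED))
    def test_every_coefficient_pinned(self, pollutant):
        intercept, coefs = PINNED[pollutant]
        model = builtin_model(pollutant)
        assert model.intercept == intercept
        assert {t.key: t.coefficient for t in model.terms} == coefs

    def test_output_units(self):
        assert builtin_model("PM2.5absorbance").output_units == "1e-5 m-1"
        for p in ("NO2", "NOx", "PM2.5", "PM10", "NO2background"):
            assert builtin_model(p).output_units == "ug m-3"

    def test_serialisation_roundtrip_identical(self):
        for model in builtin_models():
            back = model_from_dict(model_to_dict(model))
            assert back == model

    def test_mtl_alias_accepted(self):
        term = LURTerm("MTL", 500, 2.16e-08)
        assert term.predictor_id == "TML"
        assert term.key == "TML_500"

    def test_background_terms_of_no2background(self):
        keys = set(builtin_model("NO2background").term_keys())
        assert keys == {"BEO", "POP_5000", "IND_5000", "HAR_5000"}

    def test_invalid_terms_rejected(self):
        with pytest.raises(ValueError):
            LURTerm("BEO", 500, 1.0)      # backgrounds take no buffer
        with pytest.raises(ValueError):
            LURTerm("POP", None, 1.0)     # bufferable needs a radius
        with pytest.raises(ValueError):
            LURTerm("XYZ", 100, 1.0)


def _zero_stack(model):
    return {k: Raster.zeros(SPEC) for k in model.term_keys()}


class TestEvaluate:
    @pytest.mark.parametrize("pollutant,intercept",
                             [(p, v[0]) for p, v in PINNED.items()])
    def test_zero_stack_returns_intercept(self, pollutant, intercept):
        model = builtin_model(pollutant)
        out = evaluate(model, _zero_stack(model))
        np.testing.assert_array_equal(out.values, intercept)

    def test_pm10_hand_computed_value(self):
        model = builtin_model("PM10")
        stack = {
            "TML_500": Raster.full(SPEC, 1e8),
            "POP_5000": Raster.full(SPEC, 1e5),
            "MRL_50": Raster.full(SPEC, 100.0),
        }
        out = evaluate(model, stack)
        # 23.71 + 2.16 + 0.668 + 1.5
        np.testing.assert_allclose(out.values, 28.038, rtol=1e-12)

    def test_missing_term_names_it(self):
        model = builtin_model("PM10")
        stack = _zero_stack(model)
        del stack["POP_5000"]
        with pytest.raises(ValueError, match="POP_5000"):
            evaluate(model, stack)

    def test_grid_mismatch_names_term(self):
        model = builtin_model("PM10")
        stack = _zero_stack(model)
        other = GridSpec(0.0, 50.0, 5.0, 10, 11)
        stack["MRL_50"] = Raster.zeros(other)
        with pytest.raises(ValueError, match="MRL_50"):
            evaluate(model, stack)

    def test_nodata_propagates(self):
        model = builtin_model("PM10")
        stack = _zero_stack(model)
        mask = np.zeros(SPEC.shape, dtype=bool)
        mask[2, 3] = True
        stack["POP_5000"] = Raster(SPEC, np.zeros(SPEC.shape), mask)
        out = evaluate(model, stack)
        assert out.mask[2, 3] and out.mask.sum() == 1

    def test_linearity_in_stack(self):
        rng = np.random.default_rng(15)
        model = builtin_model("PM10")
        stack = {k: Raster(SPEC, rng.uniform(0, 1e6, SPEC.shape))
                 for k in model.term_keys()}
        a = 3.5
        scaled = {k: r.scaled(a) for k, r in stack.items()}
        lhs = evaluate(model, scaled).values
        rhs = model.intercept + a * (evaluate(model, stack).values
                                     - model.intercept)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_negative_cells_counted_not_clipped(self):
        model = builtin_model("NO2")  # intercept -7.8
        out = evaluate(model, _zero_stack(model))
        assert evaluation_summary(out)["n_negative"] == 100
        clipped = evaluate(model, _zero_stack(model), clip_zero=True)
        assert (clipped.values == 0.0).all()


class TestEvaluateAtPoints:
    def test_point_at_cell_center_matches_cell(self):
        model = builtin_model("PM10")
        rng = np.random.default_rng(16)
        stack = {k: Raster(SPEC, rng.uniform(0, 1e6, SPEC.shape))
                 for k in model.term_keys()}
        surface = evaluate(model, stack)
        pts = [SPEC.cell_center(3, 4), SPEC.cell_center(0, 9)]
        table = evaluate_at_points(model, stack, pts)
        assert table["value"].iloc[0] == surface.values[3, 4]
        assert table["value"].iloc[1] == surface.values[0, 9]

    def test_same_cell_same_value(self):
        model = builtin_model("PM10")
        rng = np.random.default_rng(17)
        stack = {k: Raster(SPEC, rng.uniform(0, 1e6, SPEC.shape))
                 for k in model.term_keys()}
        table = evaluate_at_points(model, stack, [(11.0, 12.0), (14.0, 13.0)])
        assert table["value"].iloc[0] == table["value"].iloc[1]

    def test_random_points_match_raster_lookup(self):
        model = builtin_model("PM10")
        rng = np.random.default_rng(18)
        stack = {k: Raster(SPEC, rng.uniform(0, 1e6, SPEC.shape))
                 for k in model.term_keys()}
        surface = evaluate(model, stack)
        pts = rng.uniform(0.0, 49.99, size=(100, 2))
        table = evaluate_at_points(model, stack, pts)
        for (x, y), v in zip(pts, table["value"]):
            assert v == surface.value_at(x, y)

    def test_outside_points_flagged_not_dropped(self):
        model = builtin_model("PM10")
        table = evaluate_at_points(model, _zero_stack(model),
                                   [(25.0, 25.0), (999.0, 999.0)])
        assert len(table) == 2
        assert table["inside"].tolist() == [True, False]
        assert np.isnan(table["value"].iloc[1])


class TestPmCoarse:
    def test_equal_inputs_zero(self):
        a = Raster.full(SPEC, 20.0)
        np.testing.assert_array_equal(derive_pm_coarse(a, a).values, 0.0)

    def test_constant_difference(self):
        out = derive_pm_coarse(Raster.full(SPEC, 20.0), Raster.full(SPEC, 12.0))
        np.testing.assert_array_equal(out.values, 8.0)

    def test_nodata_propagates(self):
        mask = np.zeros(SPEC.shape, dtype=bool)
        mask[1, 1] = True
        pm10 = Raster(SPEC, np.full(SPEC.shape, 20.0), mask)
        out = derive_pm_coarse(pm10, Raster.full(SPEC, 12.0))
        assert out.mask[1, 1] and out.mask.sum() == 1

    def test_grid_mismatch_raises(self):
        other = GridSpec(0.0, 50.0, 5.0, 10, 11)
        with pytest.raises(ValueError):
            derive_pm_coarse(Raster.zeros(SPEC), Raster.zeros(other))
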