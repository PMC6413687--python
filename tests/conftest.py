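"""Shared fixtures: small grids, the default synthetic scene, and a fully
computed predictor stack reused across end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from lurmap.grid import GridSpec, Raster
from lurmap.models import builtin_models
from lurmap.scene import SceneConfig, generate_scene, scene_predictor_stack


@pytest.fixture
def small_spec() -> GridSpec:
    """The 10x10 grid at 5 m cells used by the coordinate examples."""
    return GridSpec(x_min=0.0, y_max=50.0, cell_size=5.0, n_rows=10, n_cols=10)


def random_raster(rng, n_rows=50, n_cols=50, cell_size=5.0,
                  nodata_fraction=0.0) -> Raster:
    spec = GridSpec(0.0, n_rows * cell_size, cell_size, n_rows, n_cols)
    values = rng.normal(10.0, 4.0, size=(n_rows, n_cols))
    mask = (rng.random((n_rows, n_cols)) < nodata_fraction
            if nodata_fraction else np.zeros((n_rows, n_cols), dtype=bool))
    return Raster(spec, values, mask)


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneConfig())


#: predictor-stack builder shared by the end-to-end tests
build_stack = scene_predictor_stack


@pytest.fixture(scope="session")
def default_stack(default_scene) -> dict:
    return build_stack(default_scene)


@pytest.fixture(scope="session")
def zero_stack() -> dict:
    """All-zero predictor rasters for every term of every built-in model,
    on a tiny grid: evaluation must return the bare intercepts."""
    spec = GridSpec(0.0, 50.0, 5.0, 10, 10)
    keys = {t.key for m in builtin_models() for t in m.terms}
    return {key: Raster.zeros(spec) for key in keys}
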