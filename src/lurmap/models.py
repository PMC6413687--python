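"""The six Dutch ESCAPE land-use-regression models and their evaluation.

Each model is an intercept plus a linear combination of predictor
variables; evaluation is per-cell map algebra over a stack of predictor
rasters on one grid.  The built-in registry carries the published
coefficients verbatim; models are data (JSON-serialisable), so
user-defined models over the same predictor vocabulary are first class.

Output units follow the pollutant: concentrations in ug m^-3 except
PM2.5 absorbance, a filter-blackness proxy for elemental carbon, in
1e-5 m^-1.  Negative predicted concentrations are *not* clipped by
default — they flag use of a model outside its domain and are counted in
the evaluation summary; pass ``clip_zero=True`` to truncate at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .buffers import buffer_key
from .grid import Raster

__all__ = [
    "LURTerm",
    "LURModel",
    "builtin_models",
    "builtin_model",
    "evaluate",
    "evaluate_at_points",
    "derive_pm_coarse",
    "required_buffered_terms",
    "model_to_dict",
    "model_from_dict",
]

#: predictors that appear without a buffer (point-support surfaces)
UNBUFFERED = {"BEO", "BEX", "BEP", "BEA", "IDC", "IDM"}
BUFFERABLE = {"TL", "TML", "HTL", "RL", "MRL", "POP", "IND", "HAR", "RES"}

#: the paper trail uses both MTL and TML for major-road traffic load;
#: TML is canonical here, MTL accepted on input.
_PREDICTOR_ALIASES = {"MTL": "TML"}

POLLUTANT_UNITS = {
    "NO2": "ug m-3",
    "NO2background": "ug m-3",
    "NOx": "ug m-3",
    "PM2.5": "ug m-3",
    "PM2.5absorbance": "1e-5 m-1",
    "PM10": "ug m-3",
}


@dataclass(frozen=True)
class LURTerm:
    """One linear term: coefficient x predictor (optionally buffered).

    ``buffer`` is a radius in metres, an (inner, outer) annulus tuple, or
    None for the unbuffered surfaces (backgrounds and inverse distances).
    """

    predictor_id: str
    buffer: float | tuple[float, float] | None
    coefficient: float

    def __post_init__(self) -> None:
        pid = _PREDICTOR_ALIASES.get(self.predictor_id, self.predictor_id)
        object.__setattr__(self, "predictor_id", pid)
        if pid not in UNBUFFERED | BUFFERABLE:
            raise ValueError(f"unknown predictor id {pid!r}")
        if pid in UNBUFFERED and self.buffer is not None:
            raise ValueError(f"{pid} takes no buffer")
        if pid in BUFFERABLE and self.buffer is None:
            raise ValueError(f"{pid} requires a buffer radius")
        if isinstance(self.buffer, tuple):
            object.__setattr__(self, "buffer",
                               (float(self.buffer[0]), float(self.buffer[1])))
            if not 0 <= self.buffer[0] < self.buffer[1]:
                raise ValueError(f"bad annulus {self.buffer}")
        elif self.buffer is not None:
            object.__setattr__(self, "buffer", float(self.buffer))
            if self.buffer <= 0:
                raise ValueError(f"buffer radius must be > 0, got {self.buffer}")
        if not np.isfinite(self.coefficient):
            raise ValueError("coefficient must be finite")

    @property
    def key(self) -> str:
        return buffer_key(self.predictor_id, self.buffer)


@dataclass(frozen=True)
class LURModel:
    """Intercept + linear terms for one pollutant."""

    pollutant: str
    intercept: float
    terms: tuple[LURTerm, ...]
    output_units: str = ""

    def __post_init__(self) -> None:
        if self.pollutant in POLLUTANT_UNITS:
            expected = POLLUTANT_UNITS[self.pollutant]
            if self.output_units and self.output_units != expected:
                raise ValueError(
                    f"{self.pollutant} output units must be {expected!r}"
                )
            object.__setattr__(self, "output_units", expected)
        object.__setattr__(self, "terms", tuple(self.terms))

    def term_keys(self) -> list[str]:
        return [t.key for t in self.terms]


def _m(pollutant, intercept, *terms) -> LURModel:
    return LURModel(pollutant, intercept,
                    tuple(LURTerm(p, b, c) for (c, p, b) in terms))


def builtin_models() -> tuple[LURModel, ...]:
    """The six published Dutch LUR models (2009 annual averages).

    Coefficients are exactly the published values; a serialisation
    round-trip reproduces them bit for bit.
    """
    return (
        _m("NO2", -7.8,
           (1.18, "BEO", None),
           (2.3e-05, "POP", 5000),
           (2.47e-06, "TL", 50),
           (1.06e-4, "RL", 1000),
           (9.84e-05, "HTL", 25),
           (12.19, "IDC", None),
           (4.47e-07, "HTL", (25, 500))),
        _m("NO2background", 3.21,
           (0.74, "BEO", None),
           (2.29e-05, "POP", 5000),
           (6.4e-07, "IND", 5000),
           (4.72e-07, "HAR", 5000)),
        _m("NOx", 3.25,
           (0.74, "BEX", None),
           (4.22e-06, "TL", 50),
           (6.36e-04, "POP", 1000),
           (2.39e-06, "HTL", 500),
           (71.65, "IDM", None),
           (0.21, "MRL", 25)),
        _m("PM2.5", 9.46,
           (0.42, "BEP", None),
           (0.014, "MRL", 50),
           (2.28e-09, "TML", 1000)),
        _m("PM2.5absorbance", 0.07,
           (2.95e-09, "TL", 500),
           (0.0029, "MRL", 50),
           (0.85, "BEA", None),
           (7.90e-09, "RES", 5000),
           (1.72e-06, "HTL", 50)),
        _m("PM10", 23.71,
           (2.16e-08, "TML", 500),
           (6.68e-06, "POP", 5000),
           (0.015, "MRL", 50)),
    )


def builtin_model(pollutant: str) -> LURModel:
    for model in builtin_models():
        if model.pollutant == pollutant:
            return model
    raise ValueError(
        f"no built-in model for {pollutant!r}; choose from "
        f"{[m.pollutant for m in builtin_models()]}"
    )


def required_buffered_terms(models) -> list[tuple[str, float | tuple]]:
    """Distinct (predictor_id, buffer) pairs the models need, in first-use
    order.  All six built-ins together require 16 buffered predictors."""
    seen: dict[str, tuple] = {}
    for model in models:
        for term in model.terms:
            if term.buffer is not None and term.key not in seen:
                seen[term.key] = (term.predictor_id, term.buffer)
    return list(seen.values())


# ------------------------------------------------------------- evaluation

def _stack_raster(stack, key: str) -> Raster:
    entry = stack[key]
    return entry.raster if hasattr(entry, "raster") else entry


def evaluate(model: LURModel, stack: dict, clip_zero: bool = False) -> Raster:
    """Per-cell evaluation: intercept + sum(coefficient x predictor).

    ``stack`` maps predictor keys ('BEO', 'POP_5000', 'HTL_25-500', ...)
    to rasters (or wrapper objects carrying a ``.raster``) on a common
    grid.  NODATA in any term propagates to the output cell.
    """
    missing = [k for k in model.term_keys() if k not in stack]
    if missing:
        raise ValueError(
            f"{model.pollutant}: stack lacks predictor rasters {missing}"
        )
    rasters = {k: _stack_raster(stack, k) for k in model.term_keys()}
    specs = list(rasters.values())
    if not specs:
        raise ValueError(f"{model.pollutant}: model has no terms")
    spec = specs[0].spec
    for key, r in rasters.items():
        if not r.spec.same_geometry(spec):
            raise ValueError(
                f"{model.pollutant}: predictor {key} is on a different grid"
            )
    out = np.full(spec.shape, model.intercept, dtype=np.float64)
    mask = np.zeros(spec.shape, dtype=bool)
    for term in model.terms:
        r = rasters[term.key]
        out += term.coefficient * np.where(r.mask, 0.0, r.values)
        mask |= r.mask
    if clip_zero:
        np.maximum(out, 0.0, out=out)
    return Raster(spec, out, mask)


def evaluation_summary(result: Raster) -> dict:
    """Cell counts and range of a concentration map, including the number
    of negative cells (a sign the model was applied outside its domain)."""
    valid = ~result.mask
    vals = result.values[valid]
    return {
        "n_cells": int(result.values.size),
        "n_nodata": int(result.mask.sum()),
        "n_negative": int((vals < 0).sum()),
        "min": float(vals.min()) if vals.size else float("nan"),
        "max": float(vals.max()) if vals.size else float("nan"),
        "mean": float(vals.mean()) if vals.size else float("nan"),
    }


def evaluate_at_points(model: LURModel, stack: dict, points,
                       clip_zero: bool = False) -> pd.DataFrame:
    """Model values at point coordinates: the value of the containing cell
    (cell-constant surface, no sub-cell interpolation).

    Points outside the grid extent are kept in the output flagged with
    ``inside=False`` and a NaN value, never silently dropped.
    """
    surface = evaluate(model, stack, clip_zero=clip_zero)
    rows = []
    for (x, y) in points:
        if surface.spec.contains_point(x, y):
            rows.append((x, y, surface.value_at(x, y), True))
        else:
            rows.append((x, y, float("nan"), False))
    return pd.DataFrame(rows, columns=["x", "y", "value", "inside"])


def derive_pm_coarse(pm10: Raster, pm25: Raster) -> Raster:
    """Coarse particulate matter as the cellwise difference PM10 - PM2.5.

    The difference may be negative where the two model surfaces cross;
    negative cells are reported by :func:`evaluation_summary`, not clipped.
    """
    if not pm10.spec.same_geometry(pm25.spec):
        raise ValueError("PM10 and PM2.5 rasters are on different grids")
    return pm10 - pm25


# ---------------------------------------------------------- serialisation

def model_to_dict(model: LURModel) -> dict:
    return {
        "pollutant": model.pollutant,
        "units": model.output_units,
        "intercept": model.intercept,
        "terms": [
            {
                "predictor": t.predictor_id,
                "buffer": list(t.buffer) if isinstance(t.buffer, tuple) else t.buffer,
                "coefficient": t.coefficient,
            }
            for t in model.terms
        ],
    }


def model_from_dict(doc: dict) -> LURModel:
    terms = tuple(
        LURTerm(
            predictor_id=t["predictor"],
            buffer=tuple(t["buffer"]) if isinstance(t["buffer"], list) else t["buffer"],
            coefficient=float(t["coefficient"]),
        )
        for t in doc["terms"]
    )
    return LURModel(doc["pollutant"], float(doc["intercept"]), terms,
                    doc.get("units", ""))


def save_models(models, path) -> None:
    with open(path, "w") as fh:
        json.dump([model_to_dict(m) for m in models], fh, indent=1)


def load_models(path) -> tuple[LURModel, ...]:
    with open(path) as fh:
        docs = json.load(fh)
    if isinstance(docs, dict):
        docs = [docs]
    return tuple(model_from_dict(d) for d in docs)
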