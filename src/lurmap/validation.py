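"""Validation statistics for modelled-vs-observed comparisons.

Conventions, chosen to match standard LUR validation practice:

* RMSE  = sqrt(mean((o_i - m_i)^2))
* Bias  = mean(o_i - m_i)      (observed minus modelled)
* r^2   = squared Pearson correlation of observed and modelled — symmetric
  in the two vectors, not the R^2 of a particular regression fit; users
  comparing against regression-based definitions should note the
  difference (they coincide only for a perfect fit).
* the bias significance test is a two-sided one-sample t-test of the
  differences against zero.

RMSE >= |Bias| always (Jensen), with equality iff the differences are
constant.  Station screening removes stations with *more than* a given
fraction of missing values (the conventional threshold is 20%, strictly
greater-than) and averages the survivors' series over the study period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vector import Station, StationSet

__all__ = [
    "PairedSample",
    "ValidationReport",
    "rmse",
    "bias",
    "r_squared",
    "bias_t_test",
    "validation_report",
    "screen_stations",
]


@dataclass
class PairedSample:
    """Observed and modelled values at the same locations."""

    observed: np.ndarray
    modelled: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.float64)
        self.modelled = np.asarray(self.modelled, dtype=np.float64)
        if self.observed.shape != self.modelled.shape or self.observed.ndim != 1:
            raise ValueError("observed and modelled must be 1-D and equal length")
        bad = ~(np.isfinite(self.observed) & np.isfinite(self.modelled))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} pairs contain NaN/inf; drop NODATA pairs "
                "before building a PairedSample"
            )

    @property
    def n(self) -> int:
        return int(self.observed.size)

    @property
    def differences(self) -> np.ndarray:
        return self.observed - self.modelled


def rmse(sample: PairedSample) -> float:
    """Root mean square error of observed vs modelled."""
    if sample.n == 0:
        raise ValueError("RMSE of an empty sample is undefined")
    return float(np.sqrt(np.mean(sample.differences ** 2)))


def bias(sample: PairedSample) -> float:
    """Mean difference, observed minus modelled."""
    if sample.n == 0:
        raise ValueError("bias of an empty sample is undefined")
    return float(np.mean(sample.differences))


def r_squared(sample: PairedSample) -> float:
    """Squared Pearson correlation of observed and modelled."""
    if sample.n < 2:
        raise ValueError("r^2 needs at least 2 pairs")
    o, m = sample.observed, sample.modelled
    if np.all(o == o[0]) or np.all(m == m[0]):
        raise ValueError("r^2 undefined: one of the vectors has zero variance")
    # identical vectors correlate exactly; avoid rounding in corrcoef
    if np.array_equal(o, m):
        return 1.0
    r = np.corrcoef(o, m)[0, 1]
    return float(r * r)


def bias_t_test(sample: PairedSample) -> tuple[float, float]:
    """Two-sided one-sample t-test of the differences against zero.

    Degenerate cases follow a fixed convention: identically-zero
    differences give (0, 1); constant nonzero differences have no
    within-sample variance, so the null is rejected outright with p = 0.
    """
    if sample.n < 2:
        raise ValueError("t-test needs at least 2 pairs")
    d = sample.differences
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return (0.0, 1.0)
        return (math.copysign(math.inf, d[0]), 0.0)
    t, p = stats.ttest_1samp(d, 0.0)
    return (float(t), float(p))


@dataclass
class ValidationReport:
    """One row of a validation table."""

    dataset: str
    pollutant: str
    n: int
    r2: float
    rmse: float
    bias: float
    t_statistic: float
    p_value: float

    def to_row(self) -> dict:
        return {
            "dataset": self.dataset,
            "pollutant": self.pollutant,
            "N": self.n,
            "r2": self.r2,
            "RMSE": self.rmse,
            "Bias": self.bias,
            "t": self.t_statistic,
            "p": self.p_value,
        }


def validation_report(sample: PairedSample, pollutant: str,
                      dataset: str = "") -> ValidationReport:
    t, p = bias_t_test(sample)
    return ValidationReport(
        dataset=dataset,
        pollutant=pollutant,
        n=sample.n,
        r2=r_squared(sample),
        rmse=rmse(sample),
        bias=bias(sample),
        t_statistic=t,
        p_value=p,
    )


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def screen_stations(records: pd.DataFrame,
                    max_missing_fraction: float = 0.20) -> StationSet:
    """Screen time-tagged station records and average the survivors.

    ``records`` needs columns id, x, y, value where value may be NaN for a
    missed measurement.  A station whose missing fraction is *strictly
    above* the threshold is excluded (exactly at the threshold it is
    retained); survivors get the mean of their non-missing values.
    """
    required = {"id", "x", "y", "value"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    stations = []
    for sid, grp in records.groupby("id", sort=True):
        missing = grp["value"].isna().mean()
        if missing > max_missing_fraction:
            continue
        stations.append(
            Station(
                station_id=str(sid),
                x=float(grp["x"].iloc[0]),
                y=float(grp["y"].iloc[0]),
                value=float(grp["value"].mean()),  # skips NaN
                site_type=(str(grp["site_type"].iloc[0])
                           if "site_type" in grp.columns else None),
            )
        )
    if not stations:
        import warnings

        warnings.warn("all stations screened out", stacklevel=2)
    return StationSet(stations)


def scatter_plot(sample: PairedSample, pollutant: str, units: str = "",
                 path=None):
    """Modelled-vs-measured scatter with the least-squares fit line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(sample.modelled, sample.observed, s=14, alpha=0.7)
    if sample.n >= 2 and np.ptp(sample.modelled) > 0:
        slope, icept = np.polyfit(sample.modelled, sample.observed, 1)
        xs = np.array([sample.modelled.min(), sample.modelled.max()])
        ax.plot(xs, slope * xs + icept, "r-", lw=1)
    lim = [
        min(sample.modelled.min(), sample.observed.min()),
        max(sample.modelled.max(), sample.observed.max()),
    ]
    ax.plot(lim, lim, "k--", lw=0.8, alpha=0.5)
    unit_sfx = f" ({units})" if units else ""
    ax.set_xlabel(f"modelled{unit_sfx}")
    ax.set_ylabel(f"measured{unit_sfx}")
    ax.set_title(pollutant)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
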