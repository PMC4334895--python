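"""Percentile threshold temperature and exceedance-day census.

The heat threshold theta is an empirical percentile of the daily maximum
temperature over a basis window (by default the whole study period).
Exceedance days are the analysis-season days (May-September by default)
whose tmax lies *strictly* above theta; ties at theta contribute zero
excess under the hockey-stick term either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .io import ExposureSeries

__all__ = [
    "ThresholdSpec",
    "ThresholdResult",
    "compute_threshold",
    "exceedance_census",
    "WARM_SEASON",
]

#: Analysis window: May through September.
WARM_SEASON: tuple[int, ...] = (5, 6, 7, 8, 9)

#: numpy quantile methods exposed to analysts.  "linear" is the common
#: interpolation between order statistics (R's type 7); "inverted_cdf"
#: (type 1) takes the smallest order statistic at or above the target.
QUANTILE_METHODS = ("linear", "inverted_cdf")


@dataclass(frozen=True)
class ThresholdSpec:
    """How to resolve the threshold temperature.

    Parameters
    ----------
    percentile : float
        Strictly between 0 and 100; 90 in the main analysis.
    basis_window : (date-like, date-like) or None
        Inclusive date span over which the percentile of tmax is taken;
        None means every day in the exposure series.
    season_months : tuple of int
        Months forming the analysis window for the exceedance census.
    method : str
        Empirical quantile convention, one of ``linear`` (default) or
        ``inverted_cdf``.
    """

    percentile: float = 90.0
    basis_window: tuple | None = None
    season_months: tuple[int, ...] = WARM_SEASON
    method: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ConfigError(
                f"percentile must be strictly between 0 and 100, got {self.percentile}"
            )
        if self.method not in QUANTILE_METHODS:
            raise ConfigError(
                f"method must be one of {QUANTILE_METHODS}, got {self.method!r}"
            )


@dataclass(frozen=True)
class ThresholdResult:
    """A resolved threshold: theta plus the exceedance-day census."""

    theta: float
    percentile: float
    n_exceedance_days: int
    exceedance_dates: pd.DatetimeIndex = field(repr=False)
    method: str = "linear"

    def __post_init__(self) -> None:
        if self.n_exceedance_days != len(self.exceedance_dates):
            raise ValidationError("exceedance count disagrees with date list")


def compute_threshold(exposure: ExposureSeries, spec: ThresholdSpec) -> ThresholdResult:
    """Resolve theta as the spec's percentile of tmax over the basis window
    and census the season-window days strictly above it."""
    df = exposure.frame
    if spec.basis_window is not None:
        start, end = (pd.Timestamp(x) for x in spec.basis_window)
        basis = df[(df["date"] >= start) & (df["date"] <= end)]
    else:
        basis = df
    if basis.empty:
        raise ValidationError("threshold basis window contains no days")
    theta = float(np.quantile(basis["tmax"].to_numpy(), spec.percentile / 100.0,
                              method=spec.method))
    in_season = df["date"].dt.month.isin(spec.season_months)
    exceed = df[in_season & (df["tmax"] > theta)]
    return ThresholdResult(
        theta=theta,
        percentile=spec.percentile,
        n_exceedance_days=len(exceed),
        exceedance_dates=pd.DatetimeIndex(exceed["date"]),
        method=spec.method,
    )


def exceedance_census(
    exposure: ExposureSeries,
    percentiles: list[float],
    spec: ThresholdSpec | None = None,
) -> pd.DataFrame:
    """One row per percentile: (percentile, theta, n_exceedance_days).

    Thresholds are monotone in the percentile, so day counts are
    non-increasing down the table.  ``spec`` supplies the basis window,
    season months and quantile method; its own percentile is ignored.
    """
    base = spec or ThresholdSpec()
    rows = []
    for p in percentiles:
        res = compute_threshold(
            exposure,
            ThresholdSpec(
                percentile=p,
                basis_window=base.basis_window,
                season_months=base.season_months,
                method=base.method,
            ),
        )
        rows.append(
            {"percentile": p, "theta": res.theta, "n_exceedance_days": res.n_exceedance_days}
        )
    return pd.DataFrame(rows)
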