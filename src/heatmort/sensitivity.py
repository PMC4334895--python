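"""Sensitivity sweeps over lags, threshold percentiles and pollutant adjustment.

Each grid cell re-resolves the threshold for its percentile, rebuilds the
design with its lag, refits the quasi-Poisson model and recomputes the
attributable-death accounting.  Pollutant-adjusted cells restrict the
analysis to the pollutant-covered date range; when both adjusted and
unadjusted modes are requested, an additional ``unadjusted_window`` control
row re-reports the unadjusted model on that same restricted window so the
comparison isolates adjustment from the change of window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import attribute_fit
from .exceptions import ConfigError, HeatmortError
from .glm import LAGS, ModelSpec, fit_cause
from .io import ExposureSeries, MortalitySeries
from .threshold import ThresholdSpec, compute_threshold

__all__ = ["SensitivityGrid", "run_grid"]

POLLUTANT_MODES = ("unadjusted", "adjusted")

#: columns of the long-format grid table, in output order
GRID_COLUMNS = [
    "cause", "lag", "percentile", "pollutant_mode", "window_start", "window_end",
    "theta", "n_exceedance_days", "n_days", "beta", "se_beta", "dispersion",
    "rr", "rr_ci_low", "rr_ci_high", "converged", "ad", "pct_of_cause",
    "pct_of_total",
]


@dataclass(frozen=True)
class SensitivityGrid:
    """Axes of the sweep; the cell count is the product of the axis sizes
    (plus window-control rows when both pollutant modes are requested)."""

    causes: tuple[str, ...]
    lags: tuple[str, ...] = ("lag0",)
    percentiles: tuple[float, ...] = (90.0,)
    pollutant_modes: tuple[str, ...] = ("unadjusted",)
    include_window_control: bool = True

    def __post_init__(self) -> None:
        if not (self.causes and self.lags and self.percentiles and self.pollutant_modes):
            raise ConfigError("every grid axis must be non-empty")
        for lag in self.lags:
            if lag not in LAGS:
                raise ConfigError(f"unknown lag {lag!r}")
        for mode in self.pollutant_modes:
            if mode not in POLLUTANT_MODES:
                raise ConfigError(f"unknown pollutant mode {mode!r}")


def _pollutant_window(exposure: ExposureSeries) -> tuple[pd.Timestamp, pd.Timestamp]:
    df = exposure.frame
    covered = df["pm10"].notna() & df["o3"].notna()
    if not covered.any():
        raise ConfigError("pollutant-adjusted mode requires pm10 and o3 data")
    dates = df.loc[covered, "date"]
    return dates.min(), dates.max()


def _restrict(exposure: ExposureSeries, window) -> ExposureSeries:
    df = exposure.frame
    mask = (df["date"] >= window[0]) & (df["date"] <= window[1])
    return ExposureSeries(df.loc[mask].reset_index(drop=True))


def run_grid(
    exposure: ExposureSeries,
    mortality: MortalitySeries,
    grid: SensitivityGrid,
    base_spec: ModelSpec | None = None,
    threshold_spec: ThresholdSpec | None = None,
    all_cause_label: str | None = "All cause",
) -> pd.DataFrame:
    """Run every cell and return the long-format table.

    A cell whose fit raises or fails to converge is recorded in-row with
    ``converged = False`` and NaN estimates; the grid never aborts.  The
    output is a pure function of its inputs — identical inputs give a
    byte-identical CSV.
    """
    base = base_spec or ModelSpec()
    tbase = threshold_spec or ThresholdSpec()
    rows: list[dict] = []

    for mode in grid.pollutant_modes:
        if mode == "adjusted":
            window = _pollutant_window(exposure)
            exp_m = _restrict(exposure, window)
            submodes = [("adjusted", exp_m, window, True)]
            if grid.include_window_control and "unadjusted" in grid.pollutant_modes:
                submodes.append(("unadjusted_window", exp_m, window, False))
        else:
            window = (exposure.dates[0], exposure.dates[-1])
            submodes = [("unadjusted", exposure, window, False)]

        for mode_name, exp_m, win, use_poll in submodes:
            for pct in grid.percentiles:
                thr = compute_threshold(
                    exp_m,
                    ThresholdSpec(
                        percentile=pct,
                        basis_window=tbase.basis_window,
                        season_months=tbase.season_months,
                        method=tbase.method,
                    ),
                )
                for lag in grid.lags:
                    spec = dataclasses.replace(
                        base,
                        lag=lag,
                        threshold=thr,
                        use_pm10=use_poll,
                        use_o3=use_poll,
                    )
                    for cause in grid.causes:
                        row = {
                            "cause": cause,
                            "lag": lag,
                            "percentile": pct,
                            "pollutant_mode": mode_name,
                            "window_start": win[0].date().isoformat(),
                            "window_end": win[1].date().isoformat(),
                            "theta": thr.theta,
                            "n_exceedance_days": thr.n_exceedance_days,
                        }
                        try:
                            fit, design = fit_cause(exp_m, mortality, cause, spec)
                            attr = attribute_fit(
                                fit, exp_m, mortality, spec,
                                all_cause_label=all_cause_label,
                            )
                            row.update(
                                n_days=fit.n_days,
                                beta=fit.beta,
                                se_beta=fit.se_beta,
                                dispersion=fit.dispersion,
                                rr=fit.rr,
                                rr_ci_low=fit.rr_ci_low,
                                rr_ci_high=fit.rr_ci_high,
                                converged=fit.converged,
                                ad=attr.attributable_deaths,
                                pct_of_cause=attr.pct_of_cause_raw,
                                pct_of_total=attr.pct_of_total_raw,
                            )
                        except HeatmortError:
                            row.update(
                                n_days=np.nan, beta=np.nan, se_beta=np.nan,
                                dispersion=np.nan, rr=np.nan, rr_ci_low=np.nan,
                                rr_ci_high=np.nan, converged=False, ad=np.nan,
                                pct_of_cause=np.nan, pct_of_total=np.nan,
                            )
                        rows.append(row)

    return pd.DataFrame(rows, columns=GRID_COLUMNS)
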