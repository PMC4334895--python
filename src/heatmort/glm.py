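"""Quasi-Poisson regression of daily deaths on above-threshold temperature.

Model: for day t in the warm season,

    log E[D_t] = b0 + beta * max(0, L(tmax)_t - theta) + confounders

where L is a lag transform of daily maximum temperature (same day, single
lag 1 or 2, or the moving average of lags 0-2) and the confounders are
relative humidity, air pressure, day-of-week indicators (Sunday reference),
a natural cubic spline in calendar time for the long-term trend, and
optionally PM10 and O3.  Counts are overdispersed: Var[D_t] = phi * E[D_t].
Point estimates are Poisson maximum likelihood via IRLS; standard errors
are scaled by sqrt(phi_hat) with phi_hat the Pearson chi-square divided by
the residual degrees of freedom.  The relative risk per 1 degC above the
threshold is exp(beta) with Wald 95% limits exp(beta +- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

from .exceptions import ConfigError, RankDeficiencyError
from .io import ExposureSeries, MortalitySeries
from .threshold import WARM_SEASON, ThresholdResult

__all__ = [
    "LAGS",
    "ModelSpec",
    "Design",
    "FitResult",
    "lag_transform",
    "build_design",
    "fit_quasipoisson",
    "fit_cause",
    "relative_risk",
]

LAGS = ("lag0", "lag1", "lag2", "ma02")

#: two-sided 95% normal quantile used for Wald intervals
Z95 = 1.959964


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one regression model.

    ``threshold`` may be a :class:`~heatmort.threshold.ThresholdResult` or a
    bare temperature in degC.  ``trend_df_per_year`` sets the smoothness of
    the long-term trend spline — total trend degrees of freedom are
    ``round(df_per_year * years)``, never below 2.
    """

    lag: str = "lag0"
    threshold: ThresholdResult | float = 0.0
    use_humidity: bool = True
    use_pressure: bool = True
    use_dow: bool = True
    use_trend: bool = True
    use_pm10: bool = False
    use_o3: bool = False
    trend_df_per_year: float = 1.0
    season_months: tuple[int, ...] = WARM_SEASON

    def __post_init__(self) -> None:
        if self.lag not in LAGS:
            raise ConfigError(f"lag must be one of {LAGS}, got {self.lag!r}")
        if self.use_trend and self.trend_df_per_year < 1:
            raise ConfigError("trend_df_per_year must be >= 1")

    @property
    def theta(self) -> float:
        t = self.threshold
        return float(t.theta if isinstance(t, ThresholdResult) else t)


@dataclass(frozen=True)
class Design:
    """A built design matrix with its row dates and drop log."""

    X: pd.DataFrame = field(repr=False)
    dates: pd.DatetimeIndex = field(repr=False)
    dropped: pd.DataFrame = field(repr=False)  # columns: date, reason

    @property
    def n_rows(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class FitResult:
    """Per-cause regression result.

    ``beta`` is the log relative risk per 1 degC above the threshold;
    ``dispersion`` is the Pearson overdispersion estimate; the CI bounds are
    Wald 95% limits on the RR scale.  ``params``/``bse`` carry the full
    coefficient vector for diagnostics.
    """

    cause: str
    beta: float
    se_beta: float
    dispersion: float
    rr: float
    rr_ci_low: float
    rr_ci_high: float
    n_days: int
    converged: bool
    params: dict[str, float] = field(default_factory=dict, repr=False)
    bse: dict[str, float] = field(default_factory=dict, repr=False)


def lag_transform(exposure: ExposureSeries, lag: str) -> pd.Series:
    """Lagged daily maximum temperature, indexed by date.

    The series is reindexed onto a complete daily calendar before shifting,
    so a gap in the data invalidates (NaN) exactly the days whose lag
    history it removes.  ``ma02`` is the mean of lags 0, 1 and 2 and needs
    the two preceding days.
    """
    if lag not in LAGS:
        raise ConfigError(f"lag must be one of {LAGS}, got {lag!r}")
    s = exposure.frame.set_index("date")["tmax"]
    full = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    if lag == "lag0":
        out = full
    elif lag == "lag1":
        out = full.shift(1)
    elif lag == "lag2":
        out = full.shift(2)
    else:  # ma02
        out = (full + full.shift(1) + full.shift(2)) / 3.0
    return out.loc[s.index]


def build_design(exposure: ExposureSeries, spec: ModelSpec) -> Design:
    """Assemble the regression design matrix for in-season days.

    Columns: ``const``, ``heat`` (= max(0, L(tmax) - theta)), optional
    ``humidity``/``pressure``/``pm10``/``o3``, six day-of-week indicators
    with Sunday as reference, and a natural cubic spline basis ``trend*``
    over a continuous day index.  Rows with any required covariate missing
    (including missing lag history) are dropped and logged.
    """
    df = exposure.frame
    for flag, col in (("use_pm10", "pm10"), ("use_o3", "o3")):
        if getattr(spec, flag) and df[col].isna().all():
            raise ConfigError(f"{flag} is set but column {col!r} has no data")

    lagged = lag_transform(exposure, spec.lag)
    work = df.set_index("date")
    work["lagged_tmax"] = lagged

    in_season = work.index.month.isin(spec.season_months)
    work = work.loc[in_season]

    required = ["lagged_tmax"]
    if spec.use_humidity:
        required.append("humidity")
    if spec.use_pressure:
        required.append("pressure")
    if spec.use_pm10:
        required.append("pm10")
    if spec.use_o3:
        required.append("o3")
    missing_mask = work[required].isna().any(axis=1)
    dropped = pd.DataFrame(
        {
            "date": work.index[missing_mask],
            "reason": [
                "missing: " + ",".join(c for c in required if pd.isna(work.at[d, c]))
                for d in work.index[missing_mask]
            ],
        }
    )
    work = work.loc[~missing_mask]

    X = pd.DataFrame(index=work.index)
    X["const"] = 1.0
    X["heat"] = np.maximum(0.0, work["lagged_tmax"] - spec.theta)
    if spec.use_humidity:
        X["humidity"] = work["humidity"]
    if spec.use_pressure:
        X["pressure"] = work["pressure"]
    if spec.use_pm10:
        X["pm10"] = work["pm10"]
    if spec.use_o3:
        X["o3"] = work["o3"]
    if spec.use_dow:
        # Monday=0 ... Sunday=6; Sunday is the reference level
        dow = work.index.dayofweek
        for d, name in enumerate(["mon", "tue", "wed", "thu", "fri", "sat"]):
            X[f"dow_{name}"] = (dow == d).astype(float)
    if spec.use_trend:
        t0 = df["date"].min()
        tnum = (work.index - t0).days.to_numpy(dtype=float)
        years = (df["date"].max() - t0).days / 365.25
        df_total = max(2, int(round(spec.trend_df_per_year * max(years, 1.0))))
        # the cr basis rows sum to 1 (it spans the constant); drop the first
        # column so the trend contributes df_total parameters beyond const
        basis = np.asarray(
            dmatrix(
                "cr(t, df=k) - 1", {"t": tnum, "k": df_total + 1}, return_type="matrix"
            )
        )[:, 1:]
        for j in range(basis.shape[1]):
            X[f"trend_{j + 1}"] = basis[:, j]

    # rank is checked at fit time: a degenerate-but-valid design (e.g. a
    # heat column that is identically zero because no day exceeds theta)
    # is a legitimate description of the data
    return Design(X=X, dates=pd.DatetimeIndex(work.index), dropped=dropped)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    # scale columns so the rank test is insensitive to units
    norms = np.linalg.norm(arr, axis=0)
    if (norms == 0).any():
        zero = list(X.columns[norms == 0])
        raise RankDeficiencyError(f"all-zero design columns: {zero}")
    rank = np.linalg.matrix_rank(arr / norms)
    if rank < arr.shape[1]:
        # identify a minimal set of offending columns by greedy elimination
        from numpy.linalg import matrix_rank

        cols = list(X.columns)
        bad = []
        kept = arr / norms
        while matrix_rank(kept) < kept.shape[1]:
            for j in range(kept.shape[1] - 1, -1, -1):
                reduced = np.delete(kept, j, axis=1)
                if matrix_rank(reduced) == matrix_rank(kept):
                    bad.append(cols.pop(j))
                    kept = reduced
                    break
        raise RankDeficiencyError(f"collinear design columns: {sorted(bad)}")


def fit_quasipoisson(
    X: pd.DataFrame, counts: np.ndarray | pd.Series, cause: str = ""
) -> FitResult:
    """Fit the overdispersed Poisson model.

    Coefficients are Poisson ML (IRLS, log link, convergence when the
    relative deviance change drops below 1e-8 or after 100 iterations);
    the Pearson dispersion rescales the covariance, so point estimates are
    identical to a plain Poisson fit and only the standard errors widen.
    Non-convergence is flagged on the result, never silently ignored.
    """
    y = np.asarray(counts, dtype=float)
    if len(y) != len(X):
        raise ConfigError(f"counts ({len(y)}) and design ({len(X)}) differ in length")
    if (y < 0).any():
        raise ConfigError("negative counts passed to fit_quasipoisson")
    _check_rank(X)
    model = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=100, tol=1e-8)
    names = list(X.columns)
    params = dict(zip(names, map(float, res.params)))
    bse = dict(zip(names, map(float, res.bse)))
    dispersion = float(res.scale)
    if "heat" in params:
        beta = params["heat"]
        se = bse["heat"]
        rr = float(np.exp(beta))
        lo, hi = float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))
    else:
        beta = se = rr = lo = hi = float("nan")
    return FitResult(
        cause=cause,
        beta=beta,
        se_beta=se,
        dispersion=dispersion,
        rr=rr,
        rr_ci_low=lo,
        rr_ci_high=hi,
        n_days=len(y),
        converged=bool(res.converged),
        params=params,
        bse=bse,
    )


def fit_cause(
    exposure: ExposureSeries,
    mortality: MortalitySeries,
    cause: str,
    spec: ModelSpec,
) -> tuple[FitResult, Design]:
    """Build the design for ``spec`` and fit one cause's daily counts."""
    design = build_design(exposure, spec)
    counts = mortality.align_to(design.dates)[cause]
    fit = fit_quasipoisson(design.X, counts, cause=cause)
    return fit, design


def relative_risk(fit: FitResult, delta: float = 1.0) -> tuple[float, tuple[float, float]]:
    """RR for a ``delta``-degC rise above the threshold, with Wald 95% CI."""
    rr = float(np.exp(delta * fit.beta))
    lo = float(np.exp(delta * (fit.beta - Z95 * fit.se_beta)))
    hi = float(np.exp(delta * (fit.beta + Z95 * fit.se_beta)))
    if lo > hi:
        lo, hi = hi, lo
    return rr, (lo, hi)
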