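"""Attributable fractions and attributable deaths.

For each analysis day t the day-specific relative risk relative to the
threshold reference is RR_t = exp(beta * max(0, L(tmax)_t - theta)) and the
attributable fraction is AF_t = (RR_t - 1) / RR_t, the share of that day's
deaths that would be averted were the temperature at or below the
threshold.  Attributable deaths for a cause are AD = sum_t AF_t * D_t.
AF is zero at or below the threshold, strictly below 1 always, and negative
when beta is negative (a protective association, as seen for self-harm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .exceptions import AlignmentError
from .glm import FitResult, ModelSpec, lag_transform
from .io import ExposureSeries, MortalitySeries

__all__ = [
    "AttributionResult",
    "daily_af",
    "attributable_deaths",
    "attribute_fit",
    "percent",
]


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``.

    Half-up (not banker's) rounding matches how published tables are
    typically typeset.
    """
    value = Decimal(100) * Decimal(repr(float(numerator))) / Decimal(repr(float(denominator)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AttributionResult:
    """Cause-level attributable-death accounting.

    ``attributable_deaths`` is the unrounded total; ``ad_rounded`` the
    nearest integer for display.  ``pct_of_cause`` and ``pct_of_total`` are
    the display percentages (2 dp, half-up) of AD against the cause's own
    warm-season deaths and against all-cause warm-season deaths; the
    unrounded ratios are retained alongside.
    """

    cause: str
    af_series: pd.Series = field(repr=False)
    attributable_deaths: float
    deaths_cause_season: int
    deaths_all_season: int | None
    pct_of_cause: float
    pct_of_total: float | None
    pct_of_cause_raw: float
    pct_of_total_raw: float | None

    @property
    def ad_rounded(self) -> int:
        return int(
            Decimal(repr(self.attributable_deaths)).quantize(
                Decimal(1), rounding=ROUND_HALF_UP
            )
        )


def daily_af(
    beta: float,
    exposure: ExposureSeries,
    theta: float,
    lag: str = "lag0",
    season_months: tuple[int, ...] = ModelSpec().season_months,
) -> pd.Series:
    """Day-level attributable fractions over in-season days.

    Days whose lagged tmax is undefined (missing history at the series
    start) are excluded, matching the rows the model can be fitted on.
    """
    lagged = lag_transform(exposure, lag)
    lagged = lagged[lagged.index.month.isin(season_months)].dropna()
    excess = np.maximum(0.0, lagged.to_numpy() - float(theta))
    # AF = (RR-1)/RR = 1 - exp(-beta*excess); expm1 keeps precision near 0
    # and the clamp preserves the strict AF < 1 bound where exp(-x)
    # underflows double precision
    af = -np.expm1(-float(beta) * excess)
    af = np.minimum(af, np.nextafter(1.0, 0.0))
    return pd.Series(af, index=lagged.index, name="af")


def attributable_deaths(
    af_series: pd.Series,
    mortality: MortalitySeries,
    cause: str,
    all_cause_label: str | None = "All cause",
) -> AttributionResult:
    """Sum AF_t * D_t over the analysis days and form the two proportions.

    Denominators are the warm-season totals over the same day set: the
    cause's own deaths for ``pct_of_cause`` and the all-cause column (if
    present) for ``pct_of_total``.
    """
    dates = pd.DatetimeIndex(af_series.index)
    try:
        aligned = mortality.align_to(dates)
    except AlignmentError as err:
        raise AlignmentError(f"attribution for {cause!r}: {err}") from err
    deaths = aligned[cause].to_numpy(dtype=float)
    ad = float(np.sum(af_series.to_numpy() * deaths))
    deaths_cause = int(deaths.sum())
    pct_cause = percent(ad, deaths_cause) if deaths_cause else float("nan")
    pct_cause_raw = 100.0 * ad / deaths_cause if deaths_cause else float("nan")
    if all_cause_label is not None and all_cause_label in aligned.columns:
        deaths_all = int(aligned[all_cause_label].sum())
        pct_total = percent(ad, deaths_all) if deaths_all else float("nan")
        pct_total_raw = 100.0 * ad / deaths_all if deaths_all else float("nan")
    else:
        deaths_all = None
        pct_total = None
        pct_total_raw = None
    return AttributionResult(
        cause=cause,
        af_series=af_series,
        attributable_deaths=ad,
        deaths_cause_season=deaths_cause,
        deaths_all_season=deaths_all,
        pct_of_cause=pct_cause,
        pct_of_total=pct_total,
        pct_of_cause_raw=pct_cause_raw,
        pct_of_total_raw=pct_total_raw,
    )


def attribute_fit(
    fit: FitResult,
    exposure: ExposureSeries,
    mortality: MortalitySeries,
    spec: ModelSpec,
    all_cause_label: str | None = "All cause",
) -> AttributionResult:
    """Convenience wrapper: AFs from a fitted slope under the same model
    spec (threshold, lag, season), then the AD accounting for its cause."""
    af = daily_af(
        fit.beta, exposure, spec.theta, lag=spec.lag, season_months=spec.season_months
    )
    # restrict to days both series cover
    af = af[af.index.isin(mortality.dates)]
    return attributable_deaths(af, mortality, fit.cause, all_cause_label=all_cause_label)
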