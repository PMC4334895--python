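"""Reading, writing and validation of daily exposure and mortality tables.

Two CSV dialects are used throughout:

* weather/exposure: ``date,tmax,tmean,tmin,humidity,pressure,pm10,o3``
  (ISO-8601 dates; ``pm10``/``o3`` may be blank where not measured — blanks
  are preserved as missing, never coerced to zero);
* mortality, wide form: ``date`` plus one non-negative integer column per
  cause label; or long (line-listed) form ``date,icd10,count`` which is
  aggregated against a taxonomy on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ValidationError
from .taxonomy import BUILTIN_TAXONOMY, CauseCategory


def _ranges_subset(child, parent) -> bool:
    """True when every child stem interval lies inside a parent interval."""
    return all(
        any(plo <= lo and hi <= phi for plo, phi in parent) for lo, hi in child
    )

__all__ = [
    "ExposureSeries",
    "MortalitySeries",
    "read_exposure",
    "write_exposure",
    "read_mortality",
    "write_mortality",
]

EXPOSURE_COLUMNS = ["date", "tmax", "tmean", "tmin", "humidity", "pressure", "pm10", "o3"]


def _rows(mask) -> list[int]:
    """1-based row numbers where a boolean mask is set (first ten)."""
    return [int(i) + 1 for i in np.flatnonzero(np.asarray(mask))][:10]


def _check_dates(dates: pd.Series) -> None:
    if dates.isna().any():
        raise ValidationError(f"unparseable dates at rows {_rows(dates.isna())}")
    dup = dates[dates.duplicated()]
    if len(dup):
        raise ValidationError(
            "duplicated dates: " + ", ".join(d.date().isoformat() for d in dup[:5])
        )
    if not dates.is_monotonic_increasing:
        bad = [int(i) + 2 for i in
               np.flatnonzero(np.diff(dates.to_numpy()) < np.timedelta64(0))][:10]
        raise ValidationError(f"dates not in increasing order at rows {bad}")


@dataclass(frozen=True)
class ExposureSeries:
    """Aligned daily weather and pollutant covariates for one location.

    Wraps a DataFrame with columns ``date, tmax, tmean, tmin, humidity,
    pressure, pm10, o3`` (temperatures in degC, humidity in %, pressure in
    hPa, PM10 in ug/m3, O3 in ppb; pollutants may be NaN).  Validated on
    construction: dates strictly increasing without duplicates,
    ``tmin <= tmean <= tmax`` on every row, humidity in (0, 100], pressure
    positive, pollutants non-negative where present.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"exposure table missing columns {missing}")
        df = df.loc[:, EXPOSURE_COLUMNS].reset_index(drop=True)
        df["date"] = pd.to_datetime(df["date"])
        for col in EXPOSURE_COLUMNS[1:]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        object.__setattr__(self, "frame", df)
        _check_dates(df["date"])

        rows = _rows
        core = df[["tmax", "tmean", "tmin", "humidity", "pressure"]]
        if core.isna().any().any():
            raise ValidationError(
                f"missing weather values at rows {rows(core.isna().any(axis=1))}"
            )
        bad = (df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])
        if bad.any():
            raise ValidationError(
                f"temperature ordering tmin<=tmean<=tmax violated at rows {rows(bad)}"
            )
        bad = (df["humidity"] <= 0) | (df["humidity"] > 100)
        if bad.any():
            raise ValidationError(f"humidity outside (0, 100] at rows {rows(bad)}")
        if (df["pressure"] <= 0).any():
            raise ValidationError(
                f"non-positive pressure at rows {rows(df['pressure'] <= 0)}"
            )
        for col in ("pm10", "o3"):
            bad = df[col].notna() & (df[col] < 0)
            if bad.any():
                raise ValidationError(f"negative {col} at rows {rows(bad)}")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ExposureSeries":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class MortalitySeries:
    """Daily death counts per cause label.

    Wraps a DataFrame with a ``date`` column plus one non-negative integer
    column per cause.  Every cause is present on every date (zero-filled on
    construction from long form).  When a taxonomy is supplied, subcategory
    counts are checked against their parent category wherever both columns
    exist.
    """

    frame: pd.DataFrame = field(repr=False)
    taxonomy: list[CauseCategory] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        if "date" not in df.columns:
            raise ValidationError("mortality table missing 'date' column")
        df = df.reset_index(drop=True)
        df["date"] = pd.to_datetime(df["date"])
        _check_dates(df["date"])
        causes = [c for c in df.columns if c != "date"]
        if not causes:
            raise ValidationError("mortality table has no cause columns")
        for col in causes:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(
                    f"non-numeric counts in {col!r} at rows {_rows(vals.isna())}"
                )
            if (vals < 0).any():
                raise ValidationError(
                    f"negative counts in {col!r} at rows {_rows(vals < 0)}"
                )
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError(
                    f"non-integer counts in {col!r} at rows "
                    f"{_rows(~np.isclose(vals, np.round(vals)))}"
                )
            df[col] = vals.astype(np.int64)
        object.__setattr__(self, "frame", df)
        if self.taxonomy is not None:
            by_label = {cat.label: cat for cat in self.taxonomy}
            for col in causes:
                child = by_label.get(col)
                parent = by_label.get(getattr(child, "parent", None) or "")
                # the containment invariant only applies where the child's
                # code ranges truly nest inside the parent's (presentation
                # groupings like self-harm under mental disorders do not)
                if (
                    parent is None
                    or parent.label not in df.columns
                    or not _ranges_subset(child.ranges, parent.ranges)
                ):
                    continue
                bad = df[col] > df[parent.label]
                if bad.any():
                    dates = [d.date().isoformat() for d in df.loc[bad, "date"][:5]]
                    raise ValidationError(
                        f"{col!r} exceeds its main category {parent.label!r} on {dates}"
                    )

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    @property
    def causes(self) -> list[str]:
        return [c for c in self.frame.columns if c != "date"]

    def counts(self, cause: str) -> pd.Series:
        """Daily counts of one cause, indexed by date."""
        if cause not in self.frame.columns:
            raise KeyError(f"unknown cause label {cause!r}")
        return self.frame.set_index("date")[cause]

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, taxonomy: list[CauseCategory] | None = None
    ) -> "MortalitySeries":
        df = pd.read_csv(path)
        if set(df.columns) == {"date", "icd10", "count"}:
            return cls.from_line_list(df, taxonomy or BUILTIN_TAXONOMY)
        return cls(df, taxonomy=taxonomy)

    @classmethod
    def from_line_list(
        cls, records: pd.DataFrame, taxonomy: list[CauseCategory]
    ) -> "MortalitySeries":
        """Aggregate line-listed deaths (date, icd10, count) into daily
        per-label counts.  A record contributes to every matching label;
        dates with no deaths for a label are zero-filled over the full
        observed date range."""
        records = records.copy()
        records["date"] = pd.to_datetime(records["date"])
        full = pd.date_range(records["date"].min(), records["date"].max(), freq="D")
        out = pd.DataFrame({"date": full})
        for cat in taxonomy:
            mask = records["icd10"].map(lambda c, cat=cat: c in cat)
            daily = records.loc[mask].groupby("date")["count"].sum()
            out[cat.label] = daily.reindex(full, fill_value=0).to_numpy()
        return cls(out, taxonomy=taxonomy)

    def align_to(self, dates: pd.DatetimeIndex) -> pd.DataFrame:
        """Rows for exactly ``dates``; raises if any are not covered."""
        indexed = self.frame.set_index("date")
        missing = dates.difference(indexed.index)
        if len(missing):
            raise AlignmentError(
                f"mortality series missing {len(missing)} requested dates, "
                f"first {missing[0].date().isoformat()}"
            )
        return indexed.loc[dates]


def read_exposure(path: str | Path) -> ExposureSeries:
    return ExposureSeries.read_csv(path)


def write_exposure(series: ExposureSeries, path: str | Path) -> None:
    series.to_csv(path)


def read_mortality(
    path: str | Path, taxonomy: list[CauseCategory] | None = None
) -> MortalitySeries:
    return MortalitySeries.read_csv(path, taxonomy=taxonomy)


def write_mortality(series: MortalitySeries, path: str | Path) -> None:
    series.to_csv(path)
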