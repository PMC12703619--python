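"""The canonical daily time-series table and calendar covariates.

Every analysis in the package consumes a :class:`DailySeries`: a
contiguous daily grid of death counts (total and by sex / age 65
split), meteorology (pressure hPa, temperatures °C, wind m/s, relative
humidity %), pollutant concentrations and/or a composite AQI, plus the
derived day-of-week and holiday calendar covariates.

Validation is strict by design: gaps in the calendar, negative counts
and stratum sums that do not add up to the total are hard errors.
Death counts are never imputed — they are the outcome; meteorology and
pollutant gaps may be linearly interpolated only when explicitly
requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COUNT_COLS = ("deaths_total", "deaths_male", "deaths_female", "deaths_ge65", "deaths_lt65")
MET_COLS = ("pressure", "temp_mean", "temp_min", "temp_max", "wind_mean", "humidity_mean")
CONC_COLS = ("pm25", "pm10", "no2", "so2", "o3", "co")
STRATA = ("total", "male", "female", "ge65", "lt65")


class SeriesValidationError(ValueError):
    """The daily table violates a structural invariant."""


@dataclass
class DailySeries:
    """Validated contiguous daily table.

    The underlying frame is indexed by calendar date and carries the
    standard column names (see module constants).  ``dow`` holds the
    weekday number (0 = Monday) and ``holiday`` a 0/1 indicator.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.frame
        if not isinstance(df.index, pd.DatetimeIndex):
            raise SeriesValidationError("index must be a DatetimeIndex of calendar days")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].strftime("%Y-%m-%d").tolist()
            raise SeriesValidationError(f"duplicate dates: {dups}")
        if not df.index.is_monotonic_increasing:
            raise SeriesValidationError("dates must be strictly increasing")
        full = pd.date_range(df.index[0], df.index[-1], freq="D")
        if len(full) != len(df):
            missing = full.difference(df.index).strftime("%Y-%m-%d").tolist()
            raise SeriesValidationError(f"calendar gap; missing dates: {missing}")

        for col in COUNT_COLS:
            if col in df:
                vals = df[col].to_numpy()
                if np.any(~np.isfinite(vals)):
                    raise SeriesValidationError(f"{col}: missing or non-finite counts")
                if np.any(vals < 0) or np.any(vals != np.floor(vals)):
                    raise SeriesValidationError(f"{col}: counts must be non-negative integers")
        self._check_sum("deaths_male", "deaths_female")
        self._check_sum("deaths_ge65", "deaths_lt65")

        if "humidity_mean" in df:
            h = df["humidity_mean"].dropna()
            if ((h < 0) | (h > 100)).any():
                raise SeriesValidationError("humidity_mean must lie in [0, 100]")
        if "wind_mean" in df:
            w = df["wind_mean"].dropna()
            if (w < 0).any():
                raise SeriesValidationError("wind_mean must be >= 0")

        has_conc = [c for c in CONC_COLS if c in df and df[c].notna().all()]
        if "aqi" not in df and not has_conc:
            raise SeriesValidationError(
                "every day needs an AQI value or at least one complete pollutant column"
            )

    def _check_sum(self, a: str, b: str) -> None:
        df = self.frame
        if a in df and b in df and "deaths_total" in df:
            bad = df.index[df[a] + df[b] != df["deaths_total"]]
            if len(bad):
                days = bad.strftime("%Y-%m-%d").tolist()
                raise SeriesValidationError(
                    f"{a} + {b} != deaths_total on: {days[:10]}"
                )

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def n_years(self) -> float:
        return len(self.frame) / 365.25

    def counts(self, stratum: str = "total") -> np.ndarray:
        if stratum not in STRATA:
            raise KeyError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
        return self.frame[f"deaths_{stratum}"].to_numpy(float)

    def has_stratum(self, stratum: str) -> bool:
        return f"deaths_{stratum}" in self.frame

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(float)

    def dow_dummies(self) -> np.ndarray:
        """Six weekday dummies contrasted against Monday (n, 6)."""
        dow = self.frame["dow"].to_numpy()
        return np.column_stack([(dow == d).astype(float) for d in range(1, 7)])

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)


def derive_calendar(index: pd.DatetimeIndex, holidays=None) -> pd.DataFrame:
    """Day-of-week (0 = Monday) and holiday indicator columns."""
    holidays = pd.to_datetime(list(holidays)) if holidays is not None else []
    return pd.DataFrame(
        {
            "dow": index.dayofweek,
            "holiday": index.isin(holidays).astype(int),
        },
        index=index,
    )


def make_daily_series(
    frame: pd.DataFrame, *, holidays=None, interpolate_covariates: bool = False
) -> DailySeries:
    """Attach calendar covariates and validate a raw daily frame.

    ``interpolate_covariates`` fills interior gaps in meteorology and
    pollutant columns by linear interpolation; counts are never touched.
    """
    df = frame.copy()
    if interpolate_covariates:
        for col in (*MET_COLS, *CONC_COLS, "aqi"):
            if col in df:
                df[col] = df[col].interpolate(method="linear", limit_area="inside")
    cal = derive_calendar(df.index, holidays)
    df["dow"] = cal["dow"]
    df["holiday"] = cal["holiday"]
    return DailySeries(df)


def read_daily_series(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    *,
    holidays=None,
    interpolate_covariates: bool = False,
) -> DailySeries:
    """Read a daily CSV into a validated :class:`DailySeries`.

    ``column_map`` maps file column names to canonical names (e.g.
    ``{"PM2.5": "pm25", "AQI": "aqi"}``); the date column must map to
    (or be named) ``date``.  Non-numeric cells are a hard error naming
    the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "date" not in df.columns:
        raise SeriesValidationError("no 'date' column after applying the column map")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesValidationError(f"unparseable date column: {exc}") from exc
    df = df.drop(columns=["date"])
    df.index = pd.DatetimeIndex(dates)

    keep = [c for c in df.columns if c in (*COUNT_COLS, *MET_COLS, *CONC_COLS, "aqi")]
    df = df[keep]
    for col in keep:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SeriesValidationError(
                f"non-numeric value in column {col!r} at row {row} "
                f"({df.index[row].date()}): {df[col].iloc[row]!r}"
            )
        df[col] = coerced
    return make_daily_series(
        df, holidays=holidays, interpolate_covariates=interpolate_covariates
    )


def lag_matrix(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Matrix of lagged copies: column k holds x shifted by k days.

    Entry (t, k) is x[t-k]; the first ``max_lag`` rows have incomplete
    lagged history and carry NaN there, so downstream fitting drops
    them.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if max_lag >= x.size:
        raise ValueError(f"max_lag={max_lag} must be smaller than the series length {x.size}")
    n = x.size
    out = np.full((n, max_lag + 1), np.nan)
    for k in range(max_lag + 1):
        out[k:, k] = x[: n - k] if k else x
    return out
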