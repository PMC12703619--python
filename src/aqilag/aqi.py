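"""Composite Air Quality Index from pollutant concentrations.

The Chinese AQI (GB3095-2012 limits, HJ633-2012 index grid) maps each
pollutant concentration to an individual sub-index (IAQI) by
piecewise-linear interpolation between standard breakpoints,

    IAQI_P = (IAQI_Hi - IAQI_Lo) / (BP_Hi - BP_Lo) * (C_P - BP_Lo) + IAQI_Lo,

and defines the composite index as the maximum over pollutants,

    AQI = max_P IAQI_P.

Pollutants whose sub-index attains that maximum are the "primary"
pollutants (reported only when AQI > 50).  Sub-indices are rounded up
to integers, following the standard's convention.  Concentrations above
the top of a pollutant's scale return the scale's top index with an
overflow flag rather than extrapolating.

Units: µg/m³ for PM2.5, PM10, NO2, SO2, O3; mg/m³ for CO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

POLLUTANTS = ("pm25", "pm10", "no2", "so2", "o3", "co")

#: AQI category labels and their upper bounds (inclusive).
CATEGORY_BOUNDS = (
    ("excellent", 50),
    ("good", 100),
    ("mild", 150),
    ("moderate", 200),
    ("heavy", 300),
    ("severe", math.inf),
)

IAQI_GRID = (0, 50, 100, 150, 200, 300, 400, 500)


@dataclass(frozen=True)
class BreakpointTable:
    """Per-pollutant (BP_Lo, BP_Hi, IAQI_Lo, IAQI_Hi) interpolation segments."""

    segments: dict[str, np.ndarray]  # pollutant -> (k, 4) array
    avg_period: dict[str, str]

    def __post_init__(self) -> None:
        for pol, seg in self.segments.items():
            seg = np.asarray(seg, dtype=float)
            if seg.ndim != 2 or seg.shape[1] != 4:
                raise ValueError(f"{pol}: segments must be (k, 4)")
            bp_lo, bp_hi, iq_lo, iq_hi = seg.T
            if np.any(bp_lo >= bp_hi) or np.any(iq_lo >= iq_hi):
                raise ValueError(f"{pol}: each segment needs BP_Lo < BP_Hi and IAQI_Lo < IAQI_Hi")
            if not (np.allclose(bp_hi[:-1], bp_lo[1:]) and np.allclose(iq_hi[:-1], iq_lo[1:])):
                raise ValueError(f"{pol}: segments must be contiguous and non-overlapping")
            grid = np.concatenate([iq_lo, iq_hi[-1:]])
            if not set(grid).issubset(set(IAQI_GRID)):
                raise ValueError(f"{pol}: index grid must follow {IAQI_GRID}")

    @property
    def pollutants(self) -> tuple[str, ...]:
        return tuple(self.segments)

    def top(self, pollutant: str) -> tuple[float, float]:
        """(highest breakpoint concentration, highest index) for a pollutant."""
        seg = self.segments[pollutant]
        return float(seg[-1, 1]), float(seg[-1, 3])


def load_breakpoints(o3_period: str = "8h") -> BreakpointTable:
    """Load the embedded Chinese-standard breakpoint table.

    ``o3_period`` selects the ozone averaging window: "8h" (daily
    maximum 8-hour mean, the default) or "1h".
    """
    with resources.files("aqilag.data").joinpath("aqi_breakpoints_cn.csv").open() as fh:
        df = pd.read_csv(fh)
    segments, period = {}, {}
    for pol, grp in df.groupby("pollutant", sort=False):
        if pol == "o3":
            grp = grp[grp["avg_period"] == o3_period]
            if grp.empty:
                raise ValueError(f"no o3 segments for averaging period {o3_period!r}")
        segments[pol] = grp[["bp_lo", "bp_hi", "iaqi_lo", "iaqi_hi"]].to_numpy(float)
        period[pol] = str(grp["avg_period"].iloc[0])
    return BreakpointTable(segments, period)


@dataclass
class AqiResult:
    """Composite AQI for one day."""

    iaqi: dict[str, int]
    aqi: int
    primary_pollutant: tuple[str, ...]
    category: str
    overflow: bool = False


def categorize(aqi: float) -> str:
    for label, hi in CATEGORY_BOUNDS:
        if aqi <= hi:
            return label
    raise AssertionError("unreachable")


def compute_iaqi(
    c, pollutant: str, table: BreakpointTable, *, rounding: str = "ceil"
):
    """Sub-index for one pollutant; scalar or vectorized over an array.

    Concentrations above the pollutant's top breakpoint are capped at
    the top index.  Returns (iaqi, overflow) where overflow marks capped
    values; scalar inputs give scalar outputs.
    """
    if pollutant not in table.segments:
        raise KeyError(f"unknown pollutant {pollutant!r}; table has {table.pollutants}")
    c_arr = np.asarray(c, dtype=float)
    scalar = c_arr.ndim == 0
    c_arr = np.atleast_1d(c_arr)
    if np.any(c_arr < 0) or not np.all(np.isfinite(c_arr)):
        raise ValueError(f"{pollutant}: concentrations must be finite and >= 0")
    seg = table.segments[pollutant]
    bp_lo, bp_hi, iq_lo, iq_hi = seg.T
    top_bp, top_iq = table.top(pollutant)
    overflow = c_arr > top_bp
    cc = np.minimum(c_arr, top_bp)
    idx = np.clip(np.searchsorted(bp_lo, cc, side="right") - 1, 0, len(bp_lo) - 1)
    val = (iq_hi[idx] - iq_lo[idx]) / (bp_hi[idx] - bp_lo[idx]) * (cc - bp_lo[idx]) + iq_lo[idx]
    if rounding == "ceil":
        # guard against 49.999999.. from float noise at exact breakpoints
        val = np.ceil(np.round(val, 9)).astype(int)
    elif rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    if scalar:
        return val[0], bool(overflow[0])
    return val, overflow


def compute_aqi(
    conc: dict[str, float], table: BreakpointTable | None = None, *, rounding: str = "ceil"
) -> AqiResult:
    """Composite AQI for a single day's concentration map.

    All pollutants whose sub-index attains the maximum are reported as
    primary (none when AQI <= 50, following the reporting convention).
    """
    if table is None:
        table = load_breakpoints()
    if not conc:
        raise ValueError("concentration map is empty")
    iaqi: dict[str, int] = {}
    overflow = False
    for pol, c in conc.items():
        v, of = compute_iaqi(c, pol, table, rounding=rounding)
        iaqi[pol] = int(v) if rounding == "ceil" else float(v)
        overflow = overflow or of
    aqi = max(iaqi.values())
    primary = tuple(p for p, v in iaqi.items() if v == aqi) if aqi > 50 else ()
    return AqiResult(iaqi, aqi, primary, categorize(aqi), overflow)


def aqi_series(
    conc: pd.DataFrame, table: BreakpointTable | None = None, *, rounding: str = "ceil"
) -> pd.DataFrame:
    """Vectorized AQI over a concentration table (one row per day).

    Columns named after pollutants in :data:`POLLUTANTS`; missing
    pollutants are simply skipped.  Returns a frame with iaqi_* columns,
    aqi, category and overflow.
    """
    if table is None:
        table = load_breakpoints()
    pols = [p for p in table.pollutants if p in conc.columns]
    if not pols:
        raise ValueError("no pollutant columns found in the input")
    out = pd.DataFrame(index=conc.index)
    overflow = np.zeros(len(conc), dtype=bool)
    for pol in pols:
        v, of = compute_iaqi(conc[pol].to_numpy(float), pol, table, rounding=rounding)
        out[f"iaqi_{pol}"] = v
        overflow |= of
    iaqi_mat = out[[f"iaqi_{p}" for p in pols]].to_numpy()
    out["aqi"] = iaqi_mat.max(axis=1)
    out["category"] = pd.Categorical(
        [categorize(v) for v in out["aqi"]], categories=[c for c, _ in CATEGORY_BOUNDS]
    )
    out["overflow"] = overflow
    return out
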