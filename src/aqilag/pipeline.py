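"""Phase-1 orchestration: per-stratum lag-risk surfaces.

Fits the configured Poisson model (one of two presets) to each
mortality stratum and evaluates single-day and cumulative relative
risks over the lag window at a configured "high-AQI day" exposure,
mirroring the lag-effect tables conventionally reported in
time-series mortality studies.

Model presets
-------------
``gam_eq``
    log mu = a + cb(AQI, l) + ns(time, 7/yr) + ns(humidity, 3)
             + ns(wind, 3) + DOW + Holiday
``dlnm_eq``
    log mu = a + cb(AQI, l) + ns(time, 7/yr) + cb(pressure, l, 3x3)
             + cb(wind, l, 3x3) + DOW + Holiday

Both control the long-term trend and seasonality with a natural cubic
spline of seven degrees of freedom per year of data and weekly
patterns with day-of-week dummies.  In ``dlnm_eq`` the meteorological
confounders enter as their own cross-bases (centered at their medians);
in ``gam_eq`` they enter as plain 3-df spline terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossbasis import CrossBasis, CrossBasisSpec, build_crossbasis, predict_rr, rr_table
from .glm import Design, FitResult, fit_poisson
from .series import DailySeries, STRATA
from .splines import SplineSpec, ns

PRESETS = ("gam_eq", "dlnm_eq")


@dataclass
class PipelineConfig:
    """Settings for the phase-1 lag-risk analysis."""

    preset: str = "gam_eq"
    max_lag: int = 7
    var_df: int | str = 3          # exposure-dimension df, or "linear"
    lag_df: int | str = 3          # lag-dimension df, or "indicator"
    df_time_per_year: int = 7
    reference: float | None = None   # default: median AQI
    eval_x: float | None = None      # default: 90th percentile AQI
    strata: tuple = STRATA
    overdispersion: str = "poisson"
    curve_points: int = 50

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; expected one of {PRESETS}")

    def crossbasis_spec(self) -> CrossBasisSpec:
        var = "linear" if self.var_df == "linear" else SplineSpec(df=int(self.var_df))
        lag = "indicator" if self.lag_df == "indicator" else SplineSpec(df=int(self.lag_df))
        return CrossBasisSpec(var, lag, self.max_lag, self.reference)


@dataclass
class StratumResult:
    """Fit and lag-risk surface for one mortality stratum."""

    stratum: str
    fit: FitResult
    rr_table: pd.DataFrame
    eval_x: float
    max_single_lag: tuple[int, float, tuple[float, float]]
    max_cumulative_lag: tuple[int, float, tuple[float, float]]
    curve: pd.DataFrame | None = None
    turning_point: float | None = None


def build_design(
    series: DailySeries, config: PipelineConfig
) -> tuple[Design, CrossBasis, np.ndarray]:
    """Assemble the preset design; returns (design, aqi cross-basis, keep-mask).

    The first ``max_lag`` rows lack complete lagged history and are
    excluded via the keep-mask (dropped, never zero-filled).
    """
    df = series.frame
    if "aqi" not in df.columns:
        raise ValueError("series has no AQI column; compute it first (aqi_series)")
    n = len(series)
    cb = build_crossbasis(series.column("aqi"), config.crossbasis_spec())
    t = np.arange(n, dtype=float)
    df_time = max(int(round(config.df_time_per_year * series.n_years)), 2)
    blocks: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones((n, 1))),
        ("crossbasis", cb.matrix),
        ("time", ns(t, df_time)),
    ]
    if config.preset == "gam_eq":
        blocks.append(("humidity", ns(series.column("humidity_mean"), 3)))
        blocks.append(("wind", ns(series.column("wind_mean"), 3)))
    else:  # dlnm_eq: meteorological confounders as their own cross-bases
        met_spec = CrossBasisSpec(
            SplineSpec(df=3), SplineSpec(df=3), config.max_lag, None
        )
        blocks.append(
            ("pressure_cb", build_crossbasis(series.column("pressure"), met_spec).matrix)
        )
        blocks.append(
            ("wind_cb", build_crossbasis(series.column("wind_mean"), met_spec).matrix)
        )
    blocks.append(("dow", series.dow_dummies()))
    holiday = series.column("holiday")
    if holiday.any():  # an all-zero indicator would be collinear noise
        blocks.append(("holiday", holiday[:, None]))
    keep = cb.complete
    trimmed = [(name, blk[keep] if blk.ndim > 1 else blk[keep]) for name, blk in blocks]
    return Design.from_blocks(trimmed), cb, keep


def exposure_response_curve(
    fit: FitResult,
    cb: CrossBasis,
    grid: np.ndarray,
    *,
    block: str = "crossbasis",
) -> pd.DataFrame:
    """Overall (lag-cumulated over 0..L) RR versus reference along a grid.

    Used for the exposure-response figure and for locating the
    minimum-risk exposure (turning point = grid argmin of RR).
    """
    rows = []
    for x in np.asarray(grid, dtype=float):
        r = predict_rr(fit, cb, float(x), "cumulative", block=block)
        rows.append(r.iloc[-1][["x", "rr", "lower95", "upper95"]])
    curve = pd.DataFrame(rows).reset_index(drop=True)
    return curve


def turning_point(curve: pd.DataFrame) -> float:
    """Exposure at the minimum of the fitted overall RR curve."""
    return float(curve["x"].iloc[int(np.argmin(curve["rr"].to_numpy()))])


def run_phase1(
    series: DailySeries,
    config: PipelineConfig | None = None,
    *,
    outdir: str | Path | None = None,
    with_curve: bool = True,
    plots: bool = False,
) -> list[StratumResult]:
    """Fit the preset model per stratum and extract the lag-risk surface.

    Missing stratum columns are skipped with a warning; non-convergent
    fits are flagged on the result, not raised.  With ``outdir`` set,
    one RR-table CSV (and optionally a diagnostic plot) is written per
    stratum.
    """
    config = config or PipelineConfig()
    design, cb, keep = build_design(series, config)
    aqi = series.column("aqi")
    eval_x = (
        float(config.eval_x)
        if config.eval_x is not None
        else float(np.quantile(aqi, 0.9))
    )
    grid = np.linspace(aqi.min(), aqi.max(), config.curve_points)

    results: list[StratumResult] = []
    for stratum in config.strata:
        if not series.has_stratum(stratum):
            import warnings

            warnings.warn(f"stratum {stratum!r} missing from the series; skipped")
            continue
        y = series.counts(stratum)[keep]
        fit = fit_poisson(y, design, overdispersion=config.overdispersion)
        table = rr_table(fit, cb, eval_x)
        single = table[table["lag_kind"] == "single"].reset_index(drop=True)
        cumul = table[table["lag_kind"] == "cumulative"].reset_index(drop=True)
        i = int(np.argmax(single["rr"].to_numpy()))  # ties -> smallest lag
        j = int(np.argmax(cumul["rr"].to_numpy()))
        res = StratumResult(
            stratum=stratum,
            fit=fit,
            rr_table=table,
            eval_x=eval_x,
            max_single_lag=(
                i,
                float(single.loc[i, "rr"]),
                (float(single.loc[i, "lower95"]), float(single.loc[i, "upper95"])),
            ),
            max_cumulative_lag=(
                j,
                float(cumul.loc[j, "rr"]),
                (float(cumul.loc[j, "lower95"]), float(cumul.loc[j, "upper95"])),
            ),
        )
        if with_curve:
            res.curve = exposure_response_curve(fit, cb, grid)
            res.turning_point = turning_point(res.curve)
        results.append(res)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for res in results:
            res.rr_table.to_csv(outdir / f"rr_table_{res.stratum}.csv", index=False)
            if res.curve is not None:
                res.curve.to_csv(outdir / f"curve_{res.stratum}.csv", index=False)
            if plots:
                _plot_stratum(res, outdir)
    return results


def _plot_stratum(res: StratumResult, outdir: Path) -> None:
    """Diagnostic figure: exposure-response curve plus lag profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3 if res.curve is not None else 2, figsize=(12, 3.5))
    axes = np.atleast_1d(axes)
    k = 0
    if res.curve is not None:
        ax = axes[k]
        ax.plot(res.curve["x"], res.curve["rr"], color="firebrick")
        ax.fill_between(
            res.curve["x"], res.curve["lower95"], res.curve["upper95"], alpha=0.2,
            color="firebrick",
        )
        ax.axhline(1.0, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("AQI")
        ax.set_ylabel("overall cumulative RR")
        k += 1
    for kind, title in (("single", "single-day lag RR"), ("cumulative", "cumulative lag RR")):
        sub = res.rr_table[res.rr_table["lag_kind"] == kind]
        ax = axes[k]
        ax.errorbar(
            sub["lag"],
            sub["rr"],
            yerr=[sub["rr"] - sub["lower95"], sub["upper95"] - sub["rr"]],
            fmt="o-",
            capsize=3,
        )
        ax.axhline(1.0, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("lag (days)")
        ax.set_title(title)
        k += 1
    fig.suptitle(f"stratum: {res.stratum} (AQI {res.eval_x:.0f} vs reference)")
    fig.tight_layout()
    fig.savefig(outdir / f"lag_effects_{res.stratum}.png", dpi=120)
    plt.close(fig)
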