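"""Joint effects of AQI and meteorology: multiplicative and additive interaction.

Both exposures are dichotomized — AQI at a policy threshold (<= good,
> polluted; the national convention uses 100) and the meteorological
variable at its turning point from the fitted exposure-response curve —
and daily counts are modelled as

    log mu_t = alpha + b1*E1 + b2*E2 + g*E1*E2.

With the doubly-unexposed cell as reference, RR10 = exp(b1),
RR01 = exp(b2), RR11 = exp(b1 + b2 + g), and the interaction measures are

    IRR  = RR11 / (RR01 * RR10) = exp(g)     (multiplicative scale)
    RERI = RR11 - RR10 - RR01 + 1            (additive scale)
    AP   = RERI / RR11                       (attributable proportion)

IRR > 1 or RERI > 0 indicates synergy, IRR < 1 or RERI < 0 antagonism.
Significance verdicts use 95% CIs: delta-method intervals on RERI/AP
from the fitted coefficient covariance, Wald interval on log IRR.  A
seeded day-resampling bootstrap is available as a sensitivity check on
the delta-method intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import Design, FitResult, fit_poisson
from .crossbasis import Z95
from .series import DailySeries


@dataclass
class InteractionInput:
    """Dichotomized daily exposures and the outcome counts."""

    y: np.ndarray
    e1: np.ndarray  # AQI: 1 = polluted
    e2: np.ndarray  # meteorology: 1 = high
    cell_days: dict[str, int]
    met_var: str = ""
    aqi_threshold: float = float("nan")
    met_split: float = float("nan")


@dataclass
class InteractionResult:
    """Relative risks, interaction measures, CIs and the verdict."""

    rr10: float
    rr10_ci: tuple[float, float]
    rr01: float
    rr01_ci: tuple[float, float]
    rr11: float
    rr11_ci: tuple[float, float]
    irr: float
    irr_ci: tuple[float, float]
    reri: float
    reri_ci: tuple[float, float]
    ap: float
    ap_ci: tuple[float, float]
    verdict: str  # synergistic | antagonistic | none
    fit: FitResult | None = None
    cell_days: dict[str, int] | None = None

    def row(self) -> dict:
        fmt = lambda v, ci: f"{v:.5f} ({ci[0]:.5f}-{ci[1]:.5f})"
        return {
            "IRR (95% CI)": fmt(self.irr, self.irr_ci),
            "RERI (95% CI)": fmt(self.reri, self.reri_ci),
            "AP (95% CI)": fmt(self.ap, self.ap_ci),
            "verdict": self.verdict,
        }


def dichotomize(
    series: DailySeries,
    met_var: str,
    turning_point: float,
    aqi_threshold: float = 100.0,
    *,
    stratum: str = "total",
    min_cell_days: int = 30,
) -> InteractionInput:
    """Split AQI and a meteorological variable into binary exposures.

    Refuses (naming the empty cell) when any of the four exposure cells
    holds no days; warns suggesting a lower AQI threshold when the
    polluted cells are sparse, as happens with clean-air series where
    very few days exceed 100.
    """
    if met_var not in series.frame.columns:
        raise KeyError(f"meteorological variable {met_var!r} not in the series")
    if not (np.isfinite(turning_point) and np.isfinite(aqi_threshold)):
        raise ValueError("thresholds must be finite")
    aqi = series.column("aqi")
    met = series.column(met_var)
    e1 = (aqi > aqi_threshold).astype(int)
    e2 = (met > turning_point).astype(int)
    cells = {
        f"({i},{j})": int(np.sum((e1 == i) & (e2 == j))) for i in (0, 1) for j in (0, 1)
    }
    empty = [k for k, v in cells.items() if v == 0]
    if empty:
        raise ValueError(
            f"exposure cell(s) {', '.join(empty)} empty "
            f"(AQI threshold {aqi_threshold}, {met_var} split {turning_point}); "
            "try a lower AQI threshold (e.g. 80)"
        )
    n_polluted = cells["(1,0)"] + cells["(1,1)"]
    if n_polluted < min_cell_days:
        import warnings

        warnings.warn(
            f"only {n_polluted} polluted days above AQI {aqi_threshold}; interaction "
            "estimates will be unstable — consider a lower aqi_threshold (e.g. 80, "
            "or a quantile of the series)",
            UserWarning,
        )
    return InteractionInput(
        y=series.counts(stratum),
        e1=e1,
        e2=e2,
        cell_days=cells,
        met_var=met_var,
        aqi_threshold=float(aqi_threshold),
        met_split=float(turning_point),
    )


def _measures(beta: np.ndarray, cov: np.ndarray) -> dict:
    """Interaction measures and delta-method CIs from (b1, b2, g) and
    their covariance block."""
    b1, b2, g = beta
    se = np.sqrt(np.diag(cov))
    rr10, rr01 = np.exp(b1), np.exp(b2)
    rr11 = np.exp(b1 + b2 + g)
    v11 = np.ones(3) @ cov @ np.ones(3)
    irr = np.exp(g)
    reri = rr11 - rr10 - rr01 + 1.0
    ap = reri / rr11

    grad_reri = np.array([rr11 - rr10, rr11 - rr01, rr11])
    se_reri = float(np.sqrt(grad_reri @ cov @ grad_reri))
    grad_ap = np.array([(rr01 - 1.0) / rr11, (rr10 - 1.0) / rr11, (rr10 + rr01 - 1.0) / rr11])
    se_ap = float(np.sqrt(grad_ap @ cov @ grad_ap))

    return {
        "rr10": rr10,
        "rr10_ci": (np.exp(b1 - Z95 * se[0]), np.exp(b1 + Z95 * se[0])),
        "rr01": rr01,
        "rr01_ci": (np.exp(b2 - Z95 * se[1]), np.exp(b2 + Z95 * se[1])),
        "rr11": rr11,
        "rr11_ci": (
            np.exp(b1 + b2 + g - Z95 * np.sqrt(v11)),
            np.exp(b1 + b2 + g + Z95 * np.sqrt(v11)),
        ),
        "irr": irr,
        "irr_ci": (np.exp(g - Z95 * se[2]), np.exp(g + Z95 * se[2])),
        "reri": reri,
        "reri_ci": (reri - Z95 * se_reri, reri + Z95 * se_reri),
        "ap": ap,
        "ap_ci": (ap - Z95 * se_ap, ap + Z95 * se_ap),
    }


def _verdict(reri_ci: tuple[float, float]) -> str:
    lo, hi = reri_ci
    if lo > 0:
        return "synergistic"
    if hi < 0:
        return "antagonistic"
    return "none"


def fit_interaction(
    inp: InteractionInput,
    *,
    adjusted_blocks: list[tuple[str, np.ndarray]] | None = None,
    bootstrap: int = 0,
    seed: int = 0,
) -> InteractionResult:
    """Fit the 2x2 interaction Poisson model and compute IRR/RERI/AP.

    The default model is the unadjusted four-parameter fit; pass
    ``adjusted_blocks`` (e.g. a time-trend spline and DOW dummies) for
    a confounder-adjusted sensitivity fit.  ``bootstrap`` > 0 replaces
    the delta-method RERI/AP intervals with percentile intervals from
    that many seeded day-resampling draws.
    """
    if inp.y[(inp.e1 == 0) & (inp.e2 == 0)].sum() == 0:
        raise ValueError("reference cell (0,0) has zero total counts")
    blocks = [
        ("intercept", np.ones((inp.y.size, 1))),
        ("interaction", np.column_stack([inp.e1, inp.e2, inp.e1 * inp.e2]).astype(float)),
    ]
    if adjusted_blocks:
        blocks.extend(adjusted_blocks)
    design = Design.from_blocks(blocks)
    fit = fit_poisson(inp.y, design)
    if not fit.converged:
        raise RuntimeError("interaction model did not converge")
    m = _measures(fit.coef("interaction"), fit.coef_cov("interaction"))

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = inp.y.size
        reris, aps = [], []
        for _ in range(bootstrap):
            idx = rng.integers(0, n, n)
            e1b, e2b = inp.e1[idx], inp.e2[idx]
            if min(
                np.sum((e1b == i) & (e2b == j)) for i in (0, 1) for j in (0, 1)
            ) == 0:
                continue
            db = Design.from_blocks(
                [
                    ("intercept", np.ones((n, 1))),
                    ("interaction", np.column_stack([e1b, e2b, e1b * e2b]).astype(float)),
                ]
            )
            fb = fit_poisson(inp.y[idx], db, check_rank=False)
            mb = _measures(fb.coef("interaction"), fb.coef_cov("interaction"))
            reris.append(mb["reri"])
            aps.append(mb["ap"])
        m["reri_ci"] = tuple(np.percentile(reris, [2.5, 97.5]))
        m["ap_ci"] = tuple(np.percentile(aps, [2.5, 97.5]))

    return InteractionResult(
        **m, verdict=_verdict(m["reri_ci"]), fit=fit, cell_days=inp.cell_days
    )
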