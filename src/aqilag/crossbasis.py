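"""Cross-basis construction and lag-specific relative risks (DLNM core).

A distributed-lag nonlinear model represents the effect of an exposure
series x on the log mean of the outcome as a bidimensional surface
f(x, l) over exposure value and lag l = 0..L.  The surface is
parameterized by a tensor product of an exposure-dimension basis f_var
and a lag-dimension basis f_lag; the design row for day t is

    cb_t = sum_{l=0}^{L} ( f_var(x_{t-l}) - f_var(x0) ) (x) f_lag(l),

where x0 is the reference exposure at which the relative risk is 1 by
construction and (x) is the outer (Kronecker) product.  The exposure
basis may be a natural cubic spline or plain linear; the lag basis a
natural cubic spline over the lag grid or one indicator per lag.

After fitting a Poisson model containing the cross-basis block,
:func:`predict_rr` turns the coefficient sub-vector and its covariance
into single-lag and cumulative relative risks at any exposure value,
with delta-method (Wald) confidence intervals on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .glm import FitResult
from .splines import SplineSpec, ns_basis, resolve_spec

Z95 = 1.959963984540054  # 97.5% normal quantile


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure-dimension basis, lag-dimension basis, lag window and reference.

    ``var_spec`` is a :class:`SplineSpec` or the string "linear";
    ``lag_spec`` a :class:`SplineSpec` (evaluated on the integer lag
    grid, intercept retained so constant-in-lag effects are
    representable) or "indicator" (one column per lag).  ``reference``
    is the exposure x0 at which RR = 1; None means the series median,
    resolved at build time.
    """

    var_spec: SplineSpec | str = "linear"
    lag_spec: SplineSpec | str = "indicator"
    max_lag: int = 7
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        for name in ("var_spec", "lag_spec"):
            v = getattr(self, name)
            allowed = "linear" if name == "var_spec" else "indicator"
            if isinstance(v, str) and v != allowed:
                raise ValueError(f"{name} must be a SplineSpec or {allowed!r}")


@dataclass
class CrossBasis:
    """Expanded cross-basis design matrix plus the metadata needed for
    prediction (resolved bases, reference, exposure range)."""

    spec: CrossBasisSpec
    matrix: np.ndarray            # (n, pv * pl)
    lag_basis: np.ndarray         # (L+1, pl) rows = f_lag(l)
    var_range: tuple[float, float]
    reference: float
    complete: np.ndarray          # bool (n,); False on the first L rows

    @property
    def n_var(self) -> int:
        return 1 if self.spec.var_spec == "linear" else self.spec.var_spec.df

    @property
    def n_lag(self) -> int:
        return self.lag_basis.shape[1]

    def var_basis(self, x: np.ndarray) -> np.ndarray:
        """Exposure basis (uncentered) at arbitrary x (n, pv)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.spec.var_spec == "linear":
            return x[:, None]
        return ns_basis(x, self.spec.var_spec)

    def centered_var_basis(self, x: np.ndarray) -> np.ndarray:
        ref_row = self.var_basis(np.array([self.reference]))
        return self.var_basis(x) - ref_row


def _resolve_var_spec(x: np.ndarray, spec: CrossBasisSpec) -> CrossBasisSpec:
    if spec.var_spec == "linear":
        var = "linear"
    else:
        var = resolve_spec(x, spec.var_spec)
    ref = spec.reference if spec.reference is not None else float(np.median(x))
    return replace(spec, var_spec=var, reference=ref)


def _lag_basis(spec: CrossBasisSpec) -> np.ndarray:
    """Basis over the integer lag grid 0..L, rows f_lag(l)."""
    L = spec.max_lag
    lags = np.arange(L + 1, dtype=float)
    if spec.lag_spec == "indicator" or L == 0:
        # L = 0 degenerates to the exposure basis alone
        return np.eye(L + 1)
    ls: SplineSpec = spec.lag_spec
    if ls.df >= L + 1:
        return np.eye(L + 1)  # saturated: indicator parameterization
    resolved = SplineSpec(
        df=ls.df,
        knots=ls.knots,
        boundary=ls.boundary if ls.boundary is not None else (0.0, float(L)),
        include_intercept=True,
    )
    return ns_basis(lags, resolved)


def build_crossbasis(x: np.ndarray, spec: CrossBasisSpec) -> CrossBasis:
    """Expand an exposure series into the cross-basis design matrix.

    Rows 0..L-1 lack complete lagged history; they are built from the
    available lags only and flagged incomplete so the fitting layer
    drops them.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("exposure series must be one-dimensional")
    n = x.size
    if spec.max_lag >= n:
        raise ValueError(f"max_lag={spec.max_lag} must be smaller than the series length {n}")
    spec = _resolve_var_spec(x, spec)
    C = _lag_basis(spec)
    pl = C.shape[1]
    ref_row = (
        np.array([[spec.reference]])
        if spec.var_spec == "linear"
        else ns_basis(np.array([spec.reference]), spec.var_spec)
    )
    V = (x[:, None] if spec.var_spec == "linear" else ns_basis(x, spec.var_spec)) - ref_row
    pv = V.shape[1]

    X = np.zeros((n, pv * pl))
    for l in range(spec.max_lag + 1):
        Vl = np.zeros_like(V)
        Vl[l:] = V[: n - l] if l else V
        # vec( Vl[t] outer C[l] ) accumulated over l
        X += (Vl[:, :, None] * C[l][None, None, :]).reshape(n, pv * pl)
    complete = np.ones(n, dtype=bool)
    complete[: spec.max_lag] = False
    return CrossBasis(
        spec=spec,
        matrix=X,
        lag_basis=C,
        var_range=(float(x.min()), float(x.max())),
        reference=spec.reference,
        complete=complete,
    )


def _contrasts(cb: CrossBasis, x: float, *, extrapolate: bool = False) -> np.ndarray:
    """Per-lag contrast vectors: row l is (f_var(x) - f_var(x0)) (x) f_lag(l)."""
    lo, hi = cb.var_range
    if not extrapolate and not (lo <= x <= hi):
        raise ValueError(
            f"exposure {x} outside the observed range [{lo}, {hi}]; "
            "pass extrapolate=True to override"
        )
    u = cb.centered_var_basis(np.array([float(x)]))[0]  # (pv,)
    return np.stack(
        [(u[:, None] * cb.lag_basis[l][None, :]).reshape(-1) for l in range(cb.spec.max_lag + 1)]
    )


def predict_rr(
    fit: FitResult,
    cb: CrossBasis,
    x: float,
    mode: str = "single",
    *,
    block: str = "crossbasis",
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Relative risks at exposure ``x`` versus the reference.

    mode "single": RR attributable to exposure l days earlier, one row
    per lag.  mode "cumulative": RR from exposure accumulated over lags
    0..k (cumulative log-RR at k is the sum of single-lag log-RRs up to
    k), one row per k.  95% CIs are exp(logRR +- 1.96 SE) with the SE
    from the quadratic form of the contrast against the coefficient
    covariance.
    """
    if mode not in ("single", "cumulative"):
        raise ValueError(f"mode must be 'single' or 'cumulative', got {mode!r}")
    beta = fit.coef(block)
    cov = fit.coef_cov(block)
    contrasts = _contrasts(cb, x, extrapolate=extrapolate)
    if mode == "cumulative":
        contrasts = np.cumsum(contrasts, axis=0)
    logrr = contrasts @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrasts, cov, contrasts))
    lags = np.arange(cb.spec.max_lag + 1)
    return pd.DataFrame(
        {
            "lag_kind": mode,
            "lag": lags,
            "x": float(x),
            "logrr": logrr,
            "se": se,
            "rr": np.exp(logrr),
            "lower95": np.exp(logrr - Z95 * se),
            "upper95": np.exp(logrr + Z95 * se),
        }
    )


def rr_table(
    fit: FitResult,
    cb: CrossBasis,
    x: float,
    *,
    block: str = "crossbasis",
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Single-day (Lag0..LagL) plus cumulative (Lag00..Lag0L) RR rows,
    labelled the way lag-effect tables are conventionally printed."""
    single = predict_rr(fit, cb, x, "single", block=block, extrapolate=extrapolate)
    cumul = predict_rr(fit, cb, x, "cumulative", block=block, extrapolate=extrapolate)
    single.insert(0, "label", [f"Lag{l}" for l in single["lag"]])
    cumul.insert(0, "label", [f"Lag0{l}" for l in cumul["lag"]])
    return pd.concat([single, cumul], ignore_index=True)
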