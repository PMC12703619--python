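"""Natural cubic regression spline bases.

Natural cubic splines (``ns`` terms) are the workhorse smoother in
environmental time-series mortality models: they are piecewise cubic,
twice continuously differentiable at the knots, and constrained to be
*linear* beyond the boundary knots, which tames the wild extrapolation
of unconstrained cubics.  This module builds fixed-df (unpenalized)
natural spline design matrices used for the long-term time trend,
humidity and wind-speed confounder terms, and the exposure/lag
dimensions of the cross-basis.

Construction follows the standard B-spline route: a cubic B-spline
basis on the knot sequence is projected onto the null space of the two
second-derivative constraints at the boundary knots.  For points
outside the boundary the basis is continued linearly via a first-order
Taylor expansion at the nearest boundary knot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a natural cubic spline basis.

    Parameters
    ----------
    df
        Basis dimension (number of columns, excluding the intercept
        unless ``include_intercept``).
    knots
        Interior knot positions.  When ``None`` they are placed at
        equally spaced quantiles of the data the basis is built on.
    boundary
        The two boundary knots.  Default: data range.
    include_intercept
        If True the constant function is retained in the basis span
        (df columns still returned); if False (default) the basis is
        suitable for use alongside a separate model intercept.
    """

    df: int
    knots: tuple[float, ...] | None = None
    boundary: tuple[float, float] | None = None
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if self.knots is not None:
            k = np.asarray(self.knots, dtype=float)
            if k.ndim != 1 or np.any(np.diff(k) <= 0):
                raise ValueError("interior knots must be strictly increasing")
            object.__setattr__(self, "knots", tuple(float(v) for v in k))
        if self.boundary is not None:
            lo, hi = self.boundary
            if not lo < hi:
                raise ValueError("boundary knots must satisfy lo < hi")
            if self.knots is not None and len(self.knots) and (
                min(self.knots) <= lo or max(self.knots) >= hi
            ):
                raise ValueError("interior knots must lie strictly inside the boundary")
            object.__setattr__(self, "boundary", (float(lo), float(hi)))

    @property
    def n_interior(self) -> int:
        """Number of interior knots implied by df."""
        # natural spline space on m interior knots has dimension m + 2
        # (including the constant); dropping the constant leaves m + 1.
        return self.df - 1 if not self.include_intercept else self.df - 2


def _default_knots(x: np.ndarray, n_interior: int) -> np.ndarray:
    """Interior knots at equally spaced quantiles of x."""
    if n_interior <= 0:
        return np.empty(0)
    probs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.quantile(x, probs)


def resolve_spec(x: np.ndarray, spec: SplineSpec) -> SplineSpec:
    """Fill in data-derived knots/boundary so the spec is fully explicit."""
    x = np.asarray(x, dtype=float)
    boundary = spec.boundary if spec.boundary is not None else (float(x.min()), float(x.max()))
    if spec.knots is not None:
        knots = spec.knots
    else:
        inner = x[(x >= boundary[0]) & (x <= boundary[1])]
        knots = tuple(float(v) for v in _default_knots(inner, spec.n_interior))
    return SplineSpec(spec.df, knots, boundary, spec.include_intercept)


def _natural_transform(t: np.ndarray) -> np.ndarray:
    """Null-space projector enforcing zero second derivative at the boundary.

    ``t`` is the full (clamped) cubic knot vector.  Returns the matrix Q2
    such that B(x) @ Q2 spans the natural spline space.
    """
    m = len(t) - 4  # B-spline basis dimension
    lo, hi = t[0], t[-1]
    c2 = np.empty((2, m))
    for j in range(m):
        coef = np.zeros(m)
        coef[j] = 1.0
        b = BSpline(t, coef, 3)
        d2 = b.derivative(2)
        c2[0, j] = d2(lo)
        c2[1, j] = d2(hi)
    # QR of the constraint matrix transpose; trailing columns span the null space
    q, _ = np.linalg.qr(c2.T, mode="complete")
    return q[:, 2:]


def ns_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an (n, df) matrix.  Points beyond the boundary knots are
    evaluated by linear continuation, so every basis column is an affine
    function of x outside the boundary.

    Raises
    ------
    ValueError
        If ``df`` exceeds the number of distinct values in x (the basis
        would be rank-deficient), or the spec's knots are invalid.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if (spec.knots is None or spec.boundary is None) and spec.df > np.unique(x).size:
        # only when knots must be derived from x itself
        raise ValueError(
            f"df={spec.df} exceeds the number of distinct x values ({np.unique(x).size})"
        )
    spec = resolve_spec(x, spec)
    lo, hi = spec.boundary
    knots = np.asarray(spec.knots, dtype=float)
    t = np.concatenate([[lo] * 4, knots, [hi] * 4])

    m = len(t) - 4
    q2 = _natural_transform(t)

    # evaluate inside the boundary, linearly continue outside
    xc = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xc, t, 3, extrapolate=False).toarray()

    below, above = x < lo, x > hi
    if below.any() or above.any():
        d1 = np.empty((2, m))
        for j in range(m):
            coef = np.zeros(m)
            coef[j] = 1.0
            d1b = BSpline(t, coef, 3).derivative(1)
            d1[0, j] = d1b(lo)
            d1[1, j] = d1b(hi)
        if below.any():
            design[below] += np.outer(x[below] - lo, d1[0])
        if above.any():
            design[above] += np.outer(x[above] - hi, d1[1])

    basis = design @ q2
    if not spec.include_intercept:
        basis = basis[:, 1:]
    if basis.shape[1] != spec.df:
        raise AssertionError(
            f"basis has {basis.shape[1]} columns, expected df={spec.df}"
        )
    return basis


def ns(x: np.ndarray, df: int, **kwargs) -> np.ndarray:
    """Convenience wrapper: ``ns_basis(x, SplineSpec(df, ...))``."""
    return ns_basis(np.asarray(x, dtype=float), SplineSpec(df=df, **kwargs))
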