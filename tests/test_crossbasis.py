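"""Cross-basis design against a brute-force loop oracle; RR identities."""

import numpy as np
import pytest

from aqilag import (
    CrossBasisSpec,
    Design,
    SplineSpec,
    build_crossbasis,
    fit_poisson,
    predict_rr,
)
from aqilag.splines import ns_basis


def loop_crossbasis(x, cb):
    """Explicit double-loop construction of the cross-basis design."""
    n = len(x)
    L = cb.spec.max_lag
    V = cb.centered_var_basis(x)
    C = cb.lag_basis
    pv, pl = V.shape[1], C.shape[1]
    out = np.zeros((n, pv * pl))
    for t in range(n):
        for l in range(min(t, L) + 1):
            for i in range(pv):
                for j in range(pl):
                    out[t, i * pl + j] += V[t - l, i] * C[l, j]
    return out


@pytest.fixture(scope="module")
def random_series():
    rng = np.random.default_rng(21)
    return rng.uniform(10, 180, 400)


class TestConstruction:
    def test_constant_series_at_reference_gives_zero_design(self):
        x = np.full(50, 44.0)
        cb = build_crossbasis(
            x, CrossBasisSpec("linear", "indicator", 3, reference=44.0)
        )
        assert np.allclose(cb.matrix, 0.0)

    def test_linear_indicator_reduces_to_lagged_exposures(self):
        x = np.arange(10.0)
        cb = build_crossbasis(x, CrossBasisSpec("linear", "indicator", 2, reference=0.0))
        assert cb.matrix.shape == (10, 3)
        for t in range(2, 10):
            np.testing.assert_allclose(cb.matrix[t], [x[t], x[t - 1], x[t - 2]])

    @pytest.mark.parametrize(
        "var_spec,lag_spec",
        [
            ("linear", "indicator"),
            (SplineSpec(df=3), SplineSpec(df=3)),
            (SplineSpec(df=4), "indicator"),
            ("linear", SplineSpec(df=3)),
        ],
    )
    def test_matches_loop_oracle(self, random_series, var_spec, lag_spec):
        cb = build_crossbasis(random_series, CrossBasisSpec(var_spec, lag_spec, 7))
        oracle = loop_crossbasis(random_series, cb)
        keep = cb.complete
        assert np.max(np.abs(cb.matrix[keep] - oracle[keep])) < 1e-10

    def test_max_lag_too_large(self):
        with pytest.raises(ValueError, match="max_lag"):
            build_crossbasis(np.arange(5.0), CrossBasisSpec(max_lag=5))

    def test_l0_collapses_to_exposure_basis(self, random_series):
        cb = build_crossbasis(
            random_series, CrossBasisSpec(SplineSpec(df=3), SplineSpec(df=3), 0)
        )
        assert cb.matrix.shape[1] == 3
        direct = cb.centered_var_basis(random_series)
        np.testing.assert_allclose(cb.matrix, direct, atol=1e-12)


def _fit_with_cb(x, cb, seed=0):
    rng = np.random.default_rng(seed)
    n = len(x)
    keep = cb.complete
    design = Design.from_blocks(
        [("intercept", np.ones((n, 1))[keep]), ("crossbasis", cb.matrix[keep])]
    )
    y = rng.poisson(np.exp(1.5 + 0.002 * (x - np.median(x))))[keep]
    return fit_poisson(y.astype(float), design)


class TestPredictRR:
    def test_reference_gives_rr_one_with_degenerate_ci(self, random_series):
        cb = build_crossbasis(
            random_series, CrossBasisSpec(SplineSpec(df=3), SplineSpec(df=3), 7)
        )
        fit = _fit_with_cb(random_series, cb)
        for mode in ("single", "cumulative"):
            r = predict_rr(fit, cb, cb.reference, mode)
            np.testing.assert_allclose(r["rr"], 1.0, atol=1e-12)
            np.testing.assert_allclose(r["lower95"], 1.0, atol=1e-12)
            np.testing.assert_allclose(r["upper95"], 1.0, atol=1e-12)

    def test_cumulative_lag0_equals_single_lag0(self, random_series):
        cb = build_crossbasis(random_series, CrossBasisSpec("linear", "indicator", 7))
        fit = _fit_with_cb(random_series, cb)
        s = predict_rr(fit, cb, 100.0, "single")
        c = predict_rr(fit, cb, 100.0, "cumulative")
        assert c.loc[0, "logrr"] == pytest.approx(s.loc[0, "logrr"], abs=1e-14)

    @pytest.mark.parametrize("lag_spec", ["indicator", SplineSpec(df=3)])
    def test_cumulation_identity_all_lags(self, random_series, lag_spec):
        cb = build_crossbasis(
            random_series, CrossBasisSpec(SplineSpec(df=3), lag_spec, 7)
        )
        fit = _fit_with_cb(random_series, cb)
        s = predict_rr(fit, cb, 120.0, "single")["logrr"].to_numpy()
        c = predict_rr(fit, cb, 120.0, "cumulative")["logrr"].to_numpy()
        np.testing.assert_allclose(c, np.cumsum(s), atol=1e-10)

    def test_outside_range_requires_extrapolate_flag(self, random_series):
        cb = build_crossbasis(random_series, CrossBasisSpec("linear", "indicator", 3))
        fit = _fit_with_cb(random_series, cb)
        with pytest.raises(ValueError, match="outside"):
            predict_rr(fit, cb, 1e4, "single")
        predict_rr(fit, cb, 1e4, "single", extrapolate=True)  # no raise

    def test_linear_indicator_matches_direct_lagged_regression(self, random_series):
        """Per-lag coefficients equal an ordinary distributed-lag fit on
        explicitly lagged exposure columns."""
        from aqilag import lag_matrix

        x = random_series
        L = 7
        cb = build_crossbasis(x, CrossBasisSpec("linear", "indicator", L))
        fit = _fit_with_cb(x, cb, seed=5)

        lm = lag_matrix(x, L)
        keep = ~np.isnan(lm).any(axis=1)
        rng = np.random.default_rng(5)
        y = rng.poisson(np.exp(1.5 + 0.002 * (x - np.median(x))))[keep]
        X = np.column_stack([np.ones(keep.sum()), lm[keep] - cb.reference])
        direct = fit_poisson(y.astype(float), X)
        np.testing.assert_allclose(fit.coef("crossbasis"), direct.beta[1:], atol=1e-8)
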