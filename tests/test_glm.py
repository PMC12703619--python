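"""Poisson IRLS engine against closed forms and independent maximizers."""

import numpy as np
import pytest

from aqilag import Design, aic_scan, fit_poisson
from aqilag.glm import RankDeficientError


def newton_poisson(y, X, tol=1e-12, max_iter=100):
    """Independent Newton-Raphson maximizer from score and Hessian."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8)) if np.allclose(X[:, 0], 1) else 0.0
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        score = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(X @ beta)
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    return beta, cov


def random_problem(rng, n=500, p=5):
    X = np.column_stack([np.ones(n), rng.normal(0, 0.5, (n, p - 1))])
    beta_true = rng.normal(0, 0.3, p)
    beta_true[0] = 1.0
    y = rng.poisson(np.exp(X @ beta_true))
    return y.astype(float), X


class TestClosedForms:
    def test_intercept_only_mle_is_sample_mean(self):
        fit = fit_poisson(np.array([1, 2, 3]), np.ones((3, 1)))
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-9)
        assert fit.fitted[0] == pytest.approx(2.0, abs=1e-8)

    def test_two_group_slope_log_ratio(self):
        # exactly Poisson-mean groups 2 and 4 -> slope log 2
        y = np.array([2, 2, 4, 4])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_poisson(y, X)
        assert fit.beta[1] == pytest.approx(np.log(2.0), abs=1e-9)


class TestOracleEquivalence:
    def test_matches_newton_raphson_on_random_problems(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            y, X = random_problem(rng)
            fit = fit_poisson(y, X)
            b, cov = newton_poisson(y, X)
            np.testing.assert_allclose(fit.beta, b, atol=1e-7)
            np.testing.assert_allclose(fit.cov, cov, rtol=1e-6, atol=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        y, X = random_problem(rng)
        fit = fit_poisson(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.aic, ref.aic, rtol=1e-8)
        np.testing.assert_allclose(fit.deviance, ref.deviance, rtol=1e-8)


class TestInvariants:
    def test_mass_balance_with_intercept(self):
        rng = np.random.default_rng(13)
        y, X = random_problem(rng)
        fit = fit_poisson(y, X)
        assert abs(fit.fitted.sum() - y.sum()) < 1e-6

    def test_cov_symmetric_psd(self):
        rng = np.random.default_rng(14)
        y, X = random_problem(rng)
        fit = fit_poisson(y, X)
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)

    def test_quasipoisson_rescales_covariance(self):
        rng = np.random.default_rng(15)
        y, X = random_problem(rng)
        # overdisperse by duplicating extremes
        y = y * rng.integers(1, 4, y.size)
        plain = fit_poisson(y, X)
        quasi = fit_poisson(y, X, overdispersion="quasipoisson")
        assert quasi.dispersion > 1
        np.testing.assert_allclose(quasi.cov, plain.cov * quasi.dispersion, rtol=1e-10)


class TestErrors:
    def test_rank_deficiency_names_blocks(self):
        n = 50
        x = np.linspace(0, 1, n)
        design = Design.from_blocks(
            [
                ("intercept", np.ones((n, 1))),
                ("a", x[:, None]),
                ("b", (2 * x)[:, None]),  # collinear with a
            ]
        )
        y = np.random.default_rng(0).poisson(2.0, n).astype(float)
        with pytest.raises(RankDeficientError, match="a|b"):
            fit_poisson(y, design)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_poisson(np.zeros(10), np.ones((10, 1)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson(np.array([1.0, -1.0]), np.ones((2, 1)))


class TestAicScan:
    def test_duplicate_candidates_identical_and_stable(self):
        rng = np.random.default_rng(16)
        y, X = random_problem(rng)
        ranked = aic_scan(y, [("m1", X), ("m2", X.copy())])
        assert ranked[0][1].aic == pytest.approx(ranked[1][1].aic)
        assert [n for n, _ in ranked] == ["m1", "m2"]

    def test_noise_column_delta_aic_bound(self):
        rng = np.random.default_rng(17)
        y, X = random_problem(rng)
        noise = rng.normal(size=(y.size, 1))
        ranked = dict(aic_scan(y, [("small", X), ("big", np.hstack([X, noise]))]))
        # adding one pure-noise column can reduce AIC by at most 2 - 0 = ...
        # theory: deviance drop >= 0 and penalty +2, so AIC(big) >= AIC(small) - 2
        assert ranked["big"].aic >= ranked["small"].aic - 2.0 - 1e-8

    def test_mismatched_rows_rejected(self):
        rng = np.random.default_rng(18)
        y, X = random_problem(rng)
        with pytest.raises(ValueError, match="rows"):
            aic_scan(y, [("m1", X), ("m2", X[:-7])])

    def test_selects_true_df_most_of_the_time(self):
        """Data simulated from a 3-df spline curve: the 3-df candidate
        wins the AIC scan in a clear majority of replicates."""
        from aqilag import ns

        rng = np.random.default_rng(19)
        n = 600
        x = np.sort(rng.uniform(0, 10, n))
        # curvy truth living exactly in the 3-df natural-spline space
        truth_basis = ns(x, 3)
        f = 1.2 + truth_basis @ np.array([1.2, -1.5, 0.9])
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            y = rng.poisson(np.exp(f)).astype(float)
            cands = [
                (f"df{df}", np.column_stack([np.ones(n), ns(x, df)]))
                for df in (1, 3, 6)
            ]
            wins += aic_scan(y, cands)[0][0] == "df3"
        assert wins >= 0.6 * n_rep
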