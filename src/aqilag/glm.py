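"""Poisson log-linear regression by iteratively reweighted least squares.

This is the single fitting engine behind every model in the package:
the distributed-lag mortality models, the confounder-adjusted variants,
and the 2x2 interaction model.  Counts are modelled as

    Y_t ~ Poisson(mu_t),   log mu_t = x_t' beta,

and beta is the maximum-likelihood estimate obtained by IRLS.  A
quasi-Poisson mode rescales the coefficient covariance by the Pearson
dispersion, for daily death series that are overdispersed relative to
the Poisson.

The design is assembled from named blocks so downstream code can pull
out the cross-basis coefficient sub-vector and its covariance without
bookkeeping index arithmetic by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

MAX_ITER = 50
DEVIANCE_RTOL = 1e-9


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the offending blocks."""


@dataclass
class Design:
    """Design matrix assembled from named column blocks."""

    matrix: np.ndarray
    block_index: dict[str, slice]

    @classmethod
    def from_blocks(cls, blocks: list[tuple[str, np.ndarray]]) -> "Design":
        cols, index, start = [], {}, 0
        for name, block in blocks:
            block = np.atleast_2d(np.asarray(block, dtype=float))
            if block.shape[0] == 1 and block.shape[1] > 1:
                block = block.T
            if block.ndim == 1:
                block = block[:, None]
            cols.append(block)
            index[name] = slice(start, start + block.shape[1])
            start += block.shape[1]
        return cls(np.hstack(cols), index)

    def block(self, name: str) -> np.ndarray:
        return self.matrix[:, self.block_index[name]]


@dataclass
class ModelSpec:
    """Model description: outcome column name, ordered design blocks,
    and the variance assumption."""

    outcome: str
    blocks: list[tuple[str, np.ndarray]] = field(default_factory=list)
    overdispersion: str = "poisson"  # or "quasipoisson"

    def design(self) -> Design:
        return Design.from_blocks(self.blocks)


@dataclass
class FitResult:
    """Fitted Poisson GLM: coefficients, covariance and fit statistics."""

    beta: np.ndarray
    cov: np.ndarray
    deviance: float
    aic: float
    loglik: float
    dispersion: float
    n_used: int
    converged: bool
    n_iter: int
    block_index: dict[str, slice]
    fitted: np.ndarray

    @property
    def n_params(self) -> int:
        return self.beta.size

    def coef(self, block: str) -> np.ndarray:
        return self.beta[self.block_index[block]]

    def coef_cov(self, block: str) -> np.ndarray:
        s = self.block_index[block]
        return self.cov[s, s]

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _check_rank(X: np.ndarray, block_index: dict[str, slice]) -> None:
    """Raise RankDeficientError naming blocks involved in collinearity."""
    # column-scale for a meaningful pivoted-QR tolerance
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    r = np.linalg.matrix_rank(X / norms, tol=1e-8 * max(X.shape))
    if r == X.shape[1]:
        return
    from scipy.linalg import qr

    _, rmat, piv = qr(X / norms, mode="economic", pivoting=True)
    bad_cols = sorted(piv[r:])
    names = sorted(
        {
            name
            for name, s in block_index.items()
            for c in bad_cols
            if s.start <= c < s.stop
        }
    )
    raise RankDeficientError(
        f"design matrix rank {r} < {X.shape[1]} columns; "
        f"collinearity involves block(s): {', '.join(names) or 'unknown'}"
    )


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def fit_poisson(
    y: np.ndarray,
    X: np.ndarray | Design,
    *,
    overdispersion: str = "poisson",
    check_rank: bool = True,
) -> FitResult:
    """Fit a Poisson log-linear model by IRLS.

    Parameters
    ----------
    y
        Non-negative integer counts.
    X
        Design matrix or a :class:`Design` with named blocks.
    overdispersion
        "poisson" (default) leaves the covariance at the inverse Fisher
        information; "quasipoisson" rescales it by the Pearson
        dispersion estimate.

    Convergence: relative deviance change below 1e-9, at most 50
    iterations.  Non-convergence is flagged on the result (with a
    warning), not raised.
    """
    if isinstance(X, Design):
        design, block_index = X.matrix, X.block_index
    else:
        design = np.asarray(X, dtype=float)
        block_index = {"all": slice(0, design.shape[1])}
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or design.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must contain non-negative integers")
    if np.all(y == 0):
        raise ValueError("outcome is identically zero; Poisson mean is degenerate")
    if overdispersion not in ("poisson", "quasipoisson"):
        raise ValueError(f"unknown overdispersion mode {overdispersion!r}")
    if check_rank:
        _check_rank(design, block_index)

    n, p = design.shape
    # column scaling for numerical conditioning; undone on the estimates
    scale = np.linalg.norm(design, axis=0) / np.sqrt(n)
    scale[scale == 0] = 1.0
    Xs = design / scale

    # initialize at the working response of mu = mean(y)
    mu = np.full(n, max(y.mean(), 1e-8))
    eta = np.log(mu)
    dev = poisson_deviance(y, mu)
    beta_s = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        w = mu  # Poisson working weights with log link
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(Xs * sw[:, None], z * sw, rcond=None)
        eta_new = Xs @ beta_new
        # step-halving guard against overshoot
        step = 1.0
        while True:
            mu_new = np.exp(np.clip(eta_new, -700, 700))
            dev_new = poisson_deviance(y, mu_new)
            if np.isfinite(dev_new) and (dev_new <= dev + 1e-8 or step < 1e-8):
                break
            step /= 2.0
            eta_new = eta + step * (Xs @ beta_new - eta)
        beta_s = beta_new if step == 1.0 else beta_s + step * (beta_new - beta_s)
        eta, mu = eta_new, mu_new
        if abs(dev - dev_new) < DEVIANCE_RTOL * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        import warnings

        warnings.warn(f"IRLS did not converge in {MAX_ITER} iterations", RuntimeWarning)

    info_s = (Xs * mu[:, None]).T @ Xs
    cov_s = np.linalg.inv(info_s)
    beta = beta_s / scale
    cov = cov_s / np.outer(scale, scale)

    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = 1.0
    if overdispersion == "quasipoisson":
        dispersion = pearson / max(n - p, 1)
        cov = cov * dispersion

    ll = poisson_loglik(y, mu)
    return FitResult(
        beta=beta,
        cov=cov,
        deviance=dev,
        aic=-2.0 * ll + 2.0 * p,
        loglik=ll,
        dispersion=dispersion,
        n_used=n,
        converged=converged,
        n_iter=it,
        block_index=block_index,
        fitted=mu,
    )


def aic_scan(
    y: np.ndarray, candidates: list[tuple[str, np.ndarray | Design]]
) -> list[tuple[str, FitResult]]:
    """Fit each candidate design to the same outcome and rank by AIC.

    All candidates must cover the same rows (AIC values are otherwise
    not comparable).  Ties are broken in favour of fewer coefficients;
    the sort is stable beyond that.
    """
    y = np.asarray(y, dtype=float)
    fits = []
    for name, X in candidates:
        nrows = X.matrix.shape[0] if isinstance(X, Design) else np.asarray(X).shape[0]
        if nrows != y.size:
            raise ValueError(
                f"candidate {name!r} has {nrows} rows but the outcome has {y.size}; "
                "AIC comparison requires identical rows"
            )
        fits.append((name, fit_poisson(y, X)))
    return sorted(fits, key=lambda kv: (kv[1].aic, kv[1].n_params))
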