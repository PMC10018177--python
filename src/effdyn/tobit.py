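"""Censored-normal (Tobit) regression by maximum likelihood.

The latent model is y* = α + x'β + ε with ε ~ N(0, σ²); the observed
response is clipped at a lower bound (default 0) and optionally an upper
bound.  The log-likelihood mixes the normal density for interior
observations with probit mass at each bound.  It is maximized in Olsen's
reparametrization (γ = β/σ, h = 1/σ), in which the objective is globally
concave, starting from the least-squares solution; with no censored
observations the estimator therefore reduces exactly to least squares.

Standard errors come from the observed information (inverse numerical
Hessian at the optimum); when unit identifiers are supplied a
cluster-robust sandwich by unit is used instead, the pragmatic default for
pooled "panel Tobit" fits.  The reported pseudo-R² is McFadden's
1 − ℓ_full/ℓ_null and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_EPS = 1e-300


class DegenerateCovariateError(ValueError):
    """A design column is constant (after normalization)."""


@dataclass
class NormalizationRecord:
    """Recorded per-column transforms, reapplicable to new data."""

    method: str
    offset: np.ndarray   # subtracted
    scale: np.ndarray    # divided by

    def apply(self, design: np.ndarray) -> np.ndarray:
        return (np.asarray(design, dtype=float) - self.offset) / self.scale


def normalize_design(design, method: str = "minmax"):
    """Column-wise min-max ([0, 1]) or z-score normalization.

    Returns ``(normalized array, NormalizationRecord)``.  Constant columns
    are rejected: they carry no information and break both transforms.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.isfinite(x).all():
        raise ValueError("design must be finite")
    names = list(design.columns) if isinstance(design, pd.DataFrame) else \
        [f"x{j}" for j in range(x.shape[1])]
    const = np.ptp(x, axis=0) == 0
    if method != "none" and const.any():
        raise DegenerateCovariateError(
            f"constant columns cannot be normalized: "
            f"{[names[j] for j in np.nonzero(const)[0]]}"
        )
    if method == "minmax":
        rec = NormalizationRecord("minmax", x.min(axis=0), np.ptp(x, axis=0))
    elif method == "zscore":
        rec = NormalizationRecord("zscore", x.mean(axis=0), x.std(axis=0, ddof=0))
    elif method == "none":
        rec = NormalizationRecord("none", np.zeros(x.shape[1]), np.ones(x.shape[1]))
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return rec.apply(x), rec


@dataclass
class TobitFit:
    params: np.ndarray         # [alpha, beta..., sigma]
    names: list[str]
    se: np.ndarray
    loglik: float
    loglik_null: float
    lr: float
    pseudo_r2: float
    n: int
    n_censored_lower: int
    n_censored_upper: int
    lower: float
    upper: float | None

    @property
    def alpha(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> np.ndarray:
        return self.params[1:-1]

    @property
    def sigma(self) -> float:
        return float(self.params[-1])

    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues()))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        zc = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.params - zc * self.se,
                                self.params + zc * self.se])


def _loglik_terms(theta, X, y, lower, upper):
    """Per-observation log-likelihood in Olsen parameters [γ, h]."""
    gamma, h = theta[:-1], theta[-1]
    xg = X @ gamma
    ll = np.empty(len(y))
    lo = y <= lower if np.isfinite(lower) else np.zeros(len(y), bool)
    hi = (y >= upper) if upper is not None else np.zeros(len(y), bool)
    mid = ~(lo | hi)
    ll[mid] = np.log(h) + stats.norm.logpdf(h * y[mid] - xg[mid])
    if lo.any():
        ll[lo] = np.log(stats.norm.cdf(h * lower - xg[lo]) + _EPS)
    if hi.any():
        ll[hi] = np.log(stats.norm.cdf(xg[hi] - h * upper) + _EPS)
    return ll


def _neg_loglik(theta, X, y, lower, upper):
    if theta[-1] <= 0:
        return np.inf
    return -float(_loglik_terms(theta, X, y, lower, upper).sum())


def _fit_mle(X, y, lower, upper, start=None, tol=1e-8, maxiter=500):
    n, p = X.shape
    if start is None:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        sigma0 = max(resid.std(ddof=0), 1e-3)
        start = np.concatenate([beta0 / sigma0, [1.0 / sigma0]])
    res = optimize.minimize(
        _neg_loglik, start, args=(X, y, lower, upper), method="BFGS",
        options={"gtol": tol, "maxiter": maxiter},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"Tobit MLE did not converge: {res.message}")
    if res.x[-1] <= 0:
        raise RuntimeError("Tobit scale collapsed to a non-positive value")
    return res


def fit_tobit(design, response, lower: float = 0.0, upper: float | None = None,
              names: list[str] | None = None, add_intercept: bool = True,
              cluster: np.ndarray | None = None) -> TobitFit:
    """Fit the censored-normal regression.

    Parameters
    ----------
    design
        (n, p) covariate matrix (without intercept column unless
        ``add_intercept=False``).
    response
        Observed, possibly clipped, outcomes.
    lower, upper
        Censoring bounds; ``lower=-inf`` and ``upper=None`` disable each side.
    cluster
        Optional unit labels for cluster-robust standard errors.
    """
    X0 = np.asarray(design, dtype=float)
    if X0.ndim == 1:
        X0 = X0[:, None]
    y = np.asarray(response, dtype=float)
    if names is None:
        names = list(design.columns) if isinstance(design, pd.DataFrame) else \
            [f"x{j + 1}" for j in range(X0.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X0])
        names = ["const"] + list(names)
    else:
        X = X0
        names = list(names)
    lo_mask = y <= lower if np.isfinite(lower) else np.zeros(len(y), bool)
    hi_mask = (y >= upper) if upper is not None else np.zeros(len(y), bool)
    if (~(lo_mask | hi_mask)).sum() < 1:
        raise ValueError("need at least one uncensored observation")

    res = _fit_mle(X, y, lower, upper)
    gamma, h = res.x[:-1], res.x[-1]
    sigma = 1.0 / h
    beta = gamma * sigma
    params = np.concatenate([beta, [sigma]])
    ll = -res.fun

    # intercept-only null model for the LR statistic
    ones = np.ones((len(y), 1))
    res0 = _fit_mle(ones, y, lower, upper)
    ll0 = -res0.fun
    lr = max(2.0 * (ll - ll0), 0.0)

    se = _standard_errors(res.x, X, y, lower, upper, cluster)
    return TobitFit(
        params=params, names=names + ["sigma"], se=se,
        loglik=ll, loglik_null=ll0, lr=lr,
        pseudo_r2=float(1.0 - ll / ll0) if ll0 != 0 else np.nan,
        n=len(y), n_censored_lower=int(lo_mask.sum()),
        n_censored_upper=int(hi_mask.sum()), lower=lower, upper=upper,
    )


def _standard_errors(theta_olsen, X, y, lower, upper, cluster):
    """Delta-method SEs for (β, σ) from the Olsen-space information matrix."""
    from statsmodels.tools.numdiff import approx_fprime, approx_hess

    p = X.shape[1]
    H = approx_hess(theta_olsen, lambda t: -_neg_loglik(t, X, y, lower, upper))
    info = -H
    cov_olsen = np.linalg.inv(info)
    if cluster is not None:
        scores = approx_fprime(
            theta_olsen, lambda t: _loglik_terms(t, X, y, lower, upper)
        )
        groups = pd.Series(range(len(y))).groupby(np.asarray(cluster)).groups
        meat = np.zeros((p + 1, p + 1))
        for idx in groups.values():
            g = scores[list(idx)].sum(axis=0)
            meat += np.outer(g, g)
        cov_olsen = cov_olsen @ meat @ cov_olsen
    # transform: β = γ/h, σ = 1/h
    gamma, h = theta_olsen[:-1], theta_olsen[-1]
    J = np.zeros((p + 1, p + 1))
    J[:p, :p] = np.eye(p) / h
    J[:p, p] = -gamma / h**2
    J[p, p] = -1.0 / h**2
    cov = J @ cov_olsen @ J.T
    return np.sqrt(np.clip(np.diag(cov), 0, None))


_STARS = ((0.01, "**"), (0.05, "*"))


def report_fit(fit: TobitFit, digits: int = 3) -> pd.DataFrame:
    """Coefficient table with significance stars and 95% intervals."""
    ci = fit.conf_int()
    pvals = fit.pvalues()
    rows = []
    for j, name in enumerate(fit.names):
        stars = next((s for cut, s in _STARS if pvals[j] < cut), "")
        rows.append({
            "variable": name,
            "coef": round(float(fit.params[j]), digits),
            "se": round(float(fit.se[j]), digits),
            "z": round(float(fit.zvalues()[j]), digits),
            "p": round(float(pvals[j]), digits + 1),
            "ci_low": round(float(ci[j, 0]), digits),
            "ci_high": round(float(ci[j, 1]), digits),
            "label": f"{fit.params[j]:.{digits}f}{stars}",
        })
    return pd.DataFrame(rows)
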