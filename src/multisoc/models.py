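"""Regressions of network metrics on ecological covariates with AR1 errors.

Two models, mirroring the two levels at which windowed network metrics are
analyzed:

network level
    y_t = b0 + X_t b + e_t,   e_t = phi * e_{t-1} + eta_t,  eta ~ N(0, s^2)

node level
    y_it = b0 + u_i + X_t b + e_it,  u_i ~ N(0, tau^2), e AR1 within unit

Both are fit by exact Gaussian maximum likelihood (the AR1 series is
assumed stationary, so the first observation carries the sqrt(1 - phi^2)
weight). The network-level fit profiles (beta, sigma) out of the
likelihood and optimizes phi on (-1, 1); the node-level fit optimizes
(phi, tau, sigma) with beta profiled by GLS. 95% CIs come from the
observed-information (GLS) covariance of beta at the optimum. An optional
ridge penalty on the slopes of the network-level model shrinks estimates
the way standard-normal priors on standardized predictors would.

R^2 is the ratio var(fitted) / (var(fitted) + var(residual)) computed on
the fixed-effect fit, with a parametric-bootstrap interval.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._util import spawn_rng

log = logging.getLogger("multisoc")

__all__ = ["ModelFit", "fit_network_level", "fit_node_level", "r_squared"]

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class ModelFit:
    """Coefficients with 95% CIs plus the error-process parameters."""

    coefficients: dict  # name -> (estimate, se, lower, upper)
    phi: float
    sigma: float  # innovation SD
    random_intercept_sd: float | None
    n_obs: int
    loglik: float
    method: str = "ml"
    term_names: tuple = ()
    r_squared: tuple | None = None

    def coef(self, name: str) -> float:
        return self.coefficients[name][0]

    def ci(self, name: str) -> tuple[float, float]:
        _, _, lo, hi = self.coefficients[name]
        return lo, hi

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {
                        "term": name,
                        "estimate": est,
                        "error": se,
                        "lower_95": lo,
                        "upper_95": hi,
                    }
                    for name, (est, se, lo, hi) in self.coefficients.items()
                ],
                "phi": self.phi,
                "sigma": self.sigma,
                "random_intercept_sd": self.random_intercept_sd,
                "n_obs": self.n_obs,
                "loglik": self.loglik,
                "method": self.method,
                "r_squared": None
                if self.r_squared is None
                else dict(zip(("estimate", "lower", "upper"), self.r_squared)),
            },
            indent=2,
        )


def _design(X, term_names):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if term_names is None:
        term_names = [f"x{j + 1}" for j in range(X.shape[1])]
    return X, list(term_names)


def _whiten(y: np.ndarray, X: np.ndarray, phi: float):
    """Stationary-AR1 whitening: quasi-difference rows 2..n, scale row 1."""
    w = np.sqrt(1.0 - phi**2)
    yt = np.empty_like(y)
    Xt = np.empty_like(X)
    yt[0] = w * y[0]
    Xt[0] = w * X[0]
    yt[1:] = y[1:] - phi * y[:-1]
    Xt[1:] = X[1:] - phi * X[:-1]
    return yt, Xt


def _profiled_nll(phi, y, Xd, ridge):
    yt, Xt = _whiten(y, Xd, phi)
    n = y.size
    if ridge and ridge > 0:
        # penalty on slopes only (column 0 is the intercept); iterate the
        # sigma^2-scaled ridge to the MAP under N(0, 1/ridge) slope priors
        D = np.eye(Xd.shape[1])
        D[0, 0] = 0.0
        beta = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        for _ in range(20):
            resid = yt - Xt @ beta
            sigma2 = float(resid @ resid) / n
            beta_new = np.linalg.solve(Xt.T @ Xt + sigma2 * ridge * D, Xt.T @ yt)
            if np.allclose(beta_new, beta, rtol=1e-10, atol=1e-12):
                beta = beta_new
                break
            beta = beta_new
    else:
        beta = np.linalg.lstsq(Xt, yt, rcond=None)[0]
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * np.log(1.0 - phi**2)
    return -ll, beta, np.sqrt(sigma2), Xt


def fit_network_level(
    y: Sequence[float],
    X,
    term_names: Sequence[str] | None = None,
    ridge: float = 0.0,
    phi: float | None = None,
) -> ModelFit:
    """Fit the network-level linear model with AR1 errors by exact ML.

    ``y`` is the per-window metric series (chronological); ``X`` holds the
    standardized covariates aligned to windows (no intercept column — one
    is added). Rows with non-finite y or X are dropped listwise with a
    logged count. ``ridge`` > 0 adds a ridge penalty on the slopes
    equivalent to independent N(0, 1/ridge) priors. Passing ``phi`` fixes
    the AR1 coefficient instead of estimating it (phi=0 reduces the fit to
    ordinary least squares).
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(X, term_names)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if not keep.all():
        log.info("dropping %d windows with undefined metric or covariate", (~keep).sum())
        y, X = y[keep], X[keep]
    n = y.size
    Xd = np.column_stack([np.ones(n), X])
    if n < Xd.shape[1] + 2:
        raise ValueError("fewer observations than parameters")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response")

    if phi is None:
        res = optimize.minimize_scalar(
            lambda p: _profiled_nll(p, y, Xd, ridge)[0],
            bounds=(-0.999, 0.999),
            method="bounded",
            options={"xatol": 1e-8},
        )
        phi = float(res.x)
    elif not -1 < phi < 1:
        raise ValueError("phi must lie in (-1, 1)")
    nll, beta, sigma, Xt = _profiled_nll(phi, y, Xd, ridge)
    cov = sigma**2 * np.linalg.inv(Xt.T @ Xt)
    ses = np.sqrt(np.diag(cov))
    all_names = ["intercept", *names]
    coeffs = {
        nm: (float(b), float(se), float(b - Z95 * se), float(b + Z95 * se))
        for nm, b, se in zip(all_names, beta, ses)
    }
    return ModelFit(
        coefficients=coeffs,
        phi=phi,
        sigma=float(sigma),
        random_intercept_sd=None,
        n_obs=n,
        loglik=float(-nll),
        term_names=tuple(all_names),
    )


# ---------------------------------------------------------------------------
# node level


def _node_panels(y, X, units, times):
    """Group observations by unit, each panel sorted by time index."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    units = np.asarray(units)
    times = np.arange(y.size) if times is None else np.asarray(times)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if not keep.all():
        log.info("dropping %d rows with undefined metric or covariate", (~keep).sum())
    panels = []
    for u in sorted(set(units.tolist())):
        sel = (units == u) & keep
        if sel.sum() < 3:
            warnings.warn(f"unit {u!r} has < 3 observations; dropped")
            continue
        order = np.argsort(times[sel], kind="stable")
        panels.append((u, y[sel][order], X[sel][order], times[sel][order]))
    return panels


def _node_nll(theta, panels, p):
    phi = np.tanh(theta[0])
    tau2 = np.exp(2 * theta[1])
    sigma2 = np.exp(2 * theta[2])
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    pieces = []
    for _, yi, Xi, ti in panels:
        lag = np.abs(ti[:, None] - ti[None, :]).astype(float)
        # phi may be negative; np.power needs the sign split out for float lags
        corr = np.power(np.abs(phi), lag) * np.where(lag % 2 == 0, 1.0, np.sign(phi))
        V = tau2 + (sigma2 / (1.0 - phi**2)) * corr
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        Vi_y = np.linalg.solve(V, yi)  # reuse factor implicitly; sizes are tiny
        Vi_X = np.linalg.solve(V, Xi)
        XtVX += Xi.T @ Vi_X
        XtVy += Xi.T @ Vi_y
        pieces.append((yi, Xi, V))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    quad = 0.0
    n_total = 0
    for yi, Xi, V in pieces:
        r = yi - Xi @ beta
        quad += float(r @ np.linalg.solve(V, r))
        n_total += yi.size
    nll = 0.5 * (n_total * np.log(2 * np.pi) + logdet + quad)
    return nll, beta, XtVX


def fit_node_level(
    y: Sequence[float],
    X,
    units: Sequence[str],
    times: Sequence[int] | None = None,
    term_names: Sequence[str] | None = None,
) -> ModelFit:
    """Fit the node-level model: unit random intercepts plus within-unit
    AR1 errors, by exact ML.

    ``times`` are integer window indices per row (defaults to row order);
    the AR1 correlation between two of a unit's observations is
    phi^|t1 - t2|. Units with fewer than 3 usable rows are dropped with a
    warning.
    """
    X, names = _design(X, term_names)
    yarr = np.asarray(y, dtype=float)
    Xd = np.column_stack([np.ones(yarr.size), X])
    panels = _node_panels(yarr, Xd, units, times)
    if len(panels) < 2:
        raise ValueError("need at least 2 units with >= 3 observations each")
    p = Xd.shape[1]

    # moment-based start values
    resid_var = float(np.var(yarr[np.isfinite(yarr)]))
    start = np.array([np.arctanh(0.3), 0.5 * np.log(max(resid_var, 1e-6) / 4), 0.5 * np.log(max(resid_var, 1e-6) / 2)])
    res = optimize.minimize(
        lambda th: _node_nll(th, panels, p)[0],
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    nll, beta, XtVX = _node_nll(res.x, panels, p)
    phi = float(np.tanh(res.x[0]))
    tau = float(np.exp(res.x[1]))
    sigma = float(np.exp(res.x[2]))
    cov = np.linalg.inv(XtVX)
    ses = np.sqrt(np.diag(cov))
    all_names = ["intercept", *names]
    coeffs = {
        nm: (float(b), float(se), float(b - Z95 * se), float(b + Z95 * se))
        for nm, b, se in zip(all_names, beta, ses)
    }
    n_total = sum(len(pn[1]) for pn in panels)
    return ModelFit(
        coefficients=coeffs,
        phi=phi,
        sigma=sigma,
        random_intercept_sd=tau,
        n_obs=n_total,
        loglik=float(-nll),
        term_names=tuple(all_names),
    )


# ---------------------------------------------------------------------------
# effect size


def _fitted(fit: ModelFit, X) -> np.ndarray:
    X, _ = _design(X, None)
    beta = np.array([fit.coefficients[nm][0] for nm in fit.term_names])
    return np.column_stack([np.ones(X.shape[0]), X]) @ beta


def _simulate_ar1(n, phi, sigma, rng):
    e = np.empty(n)
    e[0] = rng.normal(0, sigma / np.sqrt(1 - phi**2))
    for t in range(1, n):
        e[t] = phi * e[t - 1] + rng.normal(0, sigma)
    return e


def r_squared(
    fit: ModelFit,
    y: Sequence[float],
    X,
    units: Sequence[str] | None = None,
    times: Sequence[int] | None = None,
    n_boot: int = 200,
    seed=None,
) -> tuple[float, float, float]:
    """Variance-explained effect size with a parametric-bootstrap interval.

    R^2 = var(fitted) / (var(fitted) + var(residual)) on the fixed-effect
    fit; the interval refits the model on ``n_boot`` datasets simulated
    from the fitted generative process (AR1 errors, plus unit intercepts
    for node-level fits). Raises when y has zero variance.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y[np.isfinite(y)]) == 0:
        raise ValueError("zero response variance; R^2 undefined")
    keep = np.isfinite(y)
    fitted = _fitted(fit, X)[keep]
    resid = y[keep] - fitted

    def gelman_r2(f, r):
        vf, vr = np.var(f), np.var(r)
        return float(vf / (vf + vr)) if vf + vr > 0 else float("nan")

    est = gelman_r2(fitted, resid)
    rng = spawn_rng(seed if seed is not None else 0, "r2boot")
    Xarr, _ = _design(X, None)
    draws = []
    for _ in range(n_boot):
        mu = _fitted(fit, Xarr)
        if fit.random_intercept_sd is None:
            ysim = mu + _simulate_ar1(mu.size, fit.phi, fit.sigma, rng)
            refit = fit_network_level(ysim, Xarr, term_names=fit.term_names[1:])
            fsim = _fitted(refit, Xarr)
            draws.append(gelman_r2(fsim, ysim - fsim))
        else:
            uarr = np.asarray(units)
            ysim = mu.copy()
            for u in sorted(set(uarr.tolist())):
                sel = uarr == u
                t = (
                    np.arange(ysim.size)[sel]
                    if times is None
                    else np.asarray(times)[sel]
                )
                order = np.argsort(t, kind="stable")
                e = _simulate_ar1(int(sel.sum()), fit.phi, fit.sigma, rng)
                ysim[np.flatnonzero(sel)[order]] += e
                ysim[sel] += rng.normal(0, fit.random_intercept_sd)
            refit = fit_node_level(
                ysim, Xarr, uarr, times=times, term_names=fit.term_names[1:]
            )
            fsim = _fitted(refit, Xarr)
            draws.append(gelman_r2(fsim, ysim - fsim))
    lo, hi = np.percentile(np.asarray(draws), [2.5, 97.5])
    return est, float(lo), float(hi)
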