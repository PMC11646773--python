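"""Generalized linear mixed models with per-subject random effects.

Two families are supported: normal with identity link, fitted by restricted
maximum likelihood (REML), and gamma with its canonical inverse link, fitted
by penalized quasi-likelihood (PQL). PQL iterates a working linearization of
the link around the current mean and fits a weighted linear mixed model to
the working response at every step; for the identity link the loop converges
after a single iteration, so both families share one solver.

The random-effect structure is a per-subject intercept plus (optionally) a
slope on the pre/post time contrast, with independent variances — the
marginal covariance is block diagonal by subject, so all linear algebra runs
block-wise on small per-subject matrices. Variance components are profiled
REML estimates optimized on the log scale; the dispersion is profiled out in
closed form.

Term tests are Wald F statistics with residual degrees of freedom
(df2 = n - p); no Kenward-Roger-style correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize, stats

from .exceptions import FitConvergenceError, ParameterError

__all__ = ["GlmmResult", "fit_glmm_core", "wald_f"]

FAMILIES = ("gaussian", "gamma")


@dataclass
class GlmmResult:
    """Converged mixed-model fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: list
    re_var: dict            # variance per random term, response-model scale
    phi: float              # dispersion (residual variance / gamma dispersion)
    family: str
    n_obs: int
    df_resid: int
    n_subjects: int
    converged: bool
    n_iter_outer: int
    boundary: bool
    subjects: np.ndarray
    random_effects: np.ndarray  # (n_subjects, q) BLUPs
    fitted_eta: np.ndarray
    fitted_mu: np.ndarray
    reml_criterion: float
    notes: list = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _blocks(groups: np.ndarray):
    uniq, inv = np.unique(groups, return_inverse=True)
    idx = [np.flatnonzero(inv == g) for g in range(len(uniq))]
    return uniq, idx


def _reml_pass(X, z, w, idx_list, Zre, log_theta0, optimize_theta=True):
    """Weighted REML linear mixed fit with relative variances theta.

    The marginal covariance of the working response is
    phi * (W^-1 + Z diag(theta) Z'), block diagonal by subject; phi is
    profiled out. Returns the profiled criterion, estimates, and BLUPs.
    """
    n, p = X.shape
    q = Zre.shape[1]
    blocks = [
        (X[ix], z[ix], Zre[ix], 1.0 / w[ix]) for ix in idx_list
    ]

    def assemble(log_theta):
        theta = np.exp(log_theta)
        XtVX = np.zeros((p, p))
        XtVz = np.zeros(p)
        ztVz = 0.0
        logdet = 0.0
        chols = []
        try:
            for Xi, zi, Zi, di in blocks:
                Vi = (Zi * theta) @ Zi.T
                Vi[np.diag_indices_from(Vi)] += di
                L = np.linalg.cholesky(Vi)
                B = sla.solve_triangular(
                    L, np.column_stack([Xi, zi]), lower=True, check_finite=False
                )
                M = B.T @ B
                XtVX += M[:p, :p]
                XtVz += M[:p, p]
                ztVz += M[p, p]
                logdet += 2.0 * np.log(np.diag(L)).sum()
                chols.append(L)
        except np.linalg.LinAlgError:
            return None
        try:
            cf = sla.cho_factor(XtVX, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return None
        beta = sla.cho_solve(cf, XtVz, check_finite=False)
        quad = ztVz - XtVz @ beta
        if not np.isfinite(quad) or quad <= 0:
            return None
        phi = quad / (n - p)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        crit = (n - p) * np.log(phi) + logdet + logdet_xvx
        return {
            "crit": crit,
            "beta": beta,
            "phi": phi,
            "XtVX": XtVX,
            "theta": theta,
            "chols": chols,
        }

    def objective(x):
        out = assemble(x)
        return out["crit"] if out is not None else 1e12

    x = np.asarray(log_theta0, dtype=float)
    if optimize_theta and q > 0:
        res = optimize.minimize(
            objective,
            x,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 400},
        )
        x = res.x
    out = assemble(x)
    if out is None:
        raise FitConvergenceError(
            "REML pass failed: working covariance not positive definite "
            f"(log variance ratios {np.array2string(x, precision=3)})"
        )
    # BLUPs: b_i = theta * Z_i' V_i^-1 (z_i - X_i beta)
    blups = np.zeros((len(blocks), q))
    for gi, ((Xi, zi, Zi, di), L) in enumerate(zip(blocks, out["chols"])):
        r = zi - Xi @ out["beta"]
        u = sla.cho_solve((L, True), r, check_finite=False)
        blups[gi] = out["theta"] * (Zi.T @ u)
    out["blups"] = blups
    out["log_theta"] = x
    return out


def fit_glmm_core(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    Zre: np.ndarray,
    family: str,
    names=None,
    max_outer: int = 60,
    tol: float = 1e-8,
) -> GlmmResult:
    """Fit the mixed model; see module docstring for the algorithm.

    ``Zre`` holds the per-observation random-effect design (a column of ones
    for the intercept, optionally a 0/1 post-session indicator for the time
    slope). ``groups`` labels the subject of each row.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    Zre = np.asarray(Zre, dtype=float)
    if family not in FAMILIES:
        raise ParameterError(f"family must be one of {FAMILIES}")
    n, p = X.shape
    if len(y) != n or len(Zre) != n:
        raise ParameterError("X, y and Zre must have matching length")
    if n <= p:
        raise ParameterError("more parameters than observations")
    uniq, idx_list = _blocks(np.asarray(groups))
    if len(uniq) < 2:
        raise ParameterError(
            "at least two subjects are required: random-effect variances are "
            "unidentifiable from a single subject"
        )
    if family == "gamma" and (y <= 0).any():
        raise ParameterError("gamma family requires strictly positive responses")
    q = Zre.shape[1]

    # initial relative variances from the crude weighted residual scatter
    def init_log_theta(z, w):
        sw = np.sqrt(w)
        coef = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)[0]
        resid = z - X @ coef
        var_w = float(np.average(resid**2, weights=w))
        return np.log(np.full(q, max(var_w * 0.05, 1e-12)))

    if family == "gaussian":
        w = np.ones(n)
        z = y
        out = _reml_pass(X, z, w, idx_list, Zre, init_log_theta(z, w))
        beta = out["beta"]
        eta = X @ beta
        for gi, ix in enumerate(idx_list):
            eta[ix] += Zre[ix] @ out["blups"][gi]
        mu = eta.copy()
        n_iter = 1
        converged = True
    else:
        mu = (y + y.mean()) / 2.0
        eta = 1.0 / mu
        out = None
        log_theta = None
        converged = False
        n_iter = 0
        delta = np.inf
        for it in range(max_outer):
            n_iter = it + 1
            w = mu**2
            z = eta - (y - mu) / mu**2
            if log_theta is None:
                log_theta = init_log_theta(z, w)
            # near convergence the working data barely move, so the variance
            # optimum is stable; skip the inner optimization then
            out = _reml_pass(
                X, z, w, idx_list, Zre, log_theta,
                optimize_theta=(it < 2 or delta > 1e-5),
            )
            log_theta = out["log_theta"]
            eta_prop = X @ out["beta"]
            for gi, ix in enumerate(idx_list):
                eta_prop[ix] += Zre[ix] @ out["blups"][gi]
            # damp toward the previous predictor if the proposal leaves the
            # positive half-line required by the inverse link
            step = 1.0
            for _ in range(30):
                eta_new = eta + step * (eta_prop - eta)
                if eta_new.min() > 1e-10:
                    break
                step *= 0.5
            else:
                raise FitConvergenceError(
                    "PQL step could not keep the linear predictor positive "
                    f"(iteration {n_iter}, min eta proposal {eta_prop.min():.3g})"
                )
            delta = np.max(np.abs(eta_new - eta)) / max(np.mean(np.abs(eta_new)), 1e-300)
            eta = eta_new
            mu = 1.0 / eta
            if delta < tol:
                converged = True
                break
        if not converged:
            raise FitConvergenceError(
                f"PQL did not converge in {max_outer} iterations; last relative "
                f"change of the linear predictor {delta:.3g} (tol {tol:g})"
            )

    theta = out["theta"]
    phi = out["phi"]
    cov_beta = phi * np.linalg.inv(out["XtVX"])
    boundary = bool((theta < 1e-7).any())
    re_names = ["intercept", "time_slope"][:q]
    re_var = {name: float(phi * th) for name, th in zip(re_names, theta)}
    if names is None:
        names = [f"x{j}" for j in range(p)]
    return GlmmResult(
        beta=out["beta"],
        cov_beta=cov_beta,
        names=list(names),
        re_var=re_var,
        phi=float(phi),
        family=family,
        n_obs=n,
        df_resid=n - p,
        n_subjects=len(uniq),
        converged=converged,
        n_iter_outer=n_iter,
        boundary=boundary,
        subjects=uniq,
        random_effects=out["blups"],
        fitted_eta=eta,
        fitted_mu=mu,
        reml_criterion=float(out["crit"]),
    )


def wald_f(result: GlmmResult, cols) -> tuple:
    """Wald F test that the coefficients in ``cols`` are jointly zero.

    Returns (F, df1, df2, p) with df2 the residual degrees of freedom.
    """
    cols = np.atleast_1d(cols)
    L = np.zeros((len(cols), len(result.beta)))
    for i, c in enumerate(cols):
        L[i, c] = 1.0
    est = L @ result.beta
    V = L @ result.cov_beta @ L.T
    F = float(est @ np.linalg.solve(V, est) / len(cols))
    df1, df2 = len(cols), result.df_resid
    pval = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, pval
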