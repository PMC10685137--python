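"""Random-intercept Gaussian mixed model fitted by direct likelihood
optimization.

Model: ``y = X b + u[group] + e`` with ``u ~ N(0, s2_u)`` i.i.d. per group and
``e ~ N(0, s2_e)``.  The fixed effects are profiled out by GLS at each
variance candidate; the per-group covariance ``s2_e I + s2_u 11'`` is handled
with the Sherman–Morrison identity, so no large matrix is ever formed.  Both
ML and REML criteria are supported; REML is the default (the variance bias of
ML matters at the sample sizes this package works with).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError

_LOG_FLOOR = -15.0  # variance boundary on the log scale


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    sigma2_e: float
    sigma2_u: float
    loglik: float
    df_resid: int
    n_groups: int
    boundary: bool

    def t_pvalues(self) -> np.ndarray:
        t = self.beta / self.se
        return 2.0 * stats.t.sf(np.abs(t), self.df_resid)


def _gls_pieces(y, X, group_slices, s2e, s2u):
    """Return (XtViX, XtViy, ytViy, logdetV) for the block covariance."""
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for sl in group_slices:
        Xg, yg = X[sl], y[sl]
        ng = len(yg)
        c = s2u / (s2e + ng * s2u)
        x1 = Xg.sum(axis=0)
        y1 = yg.sum()
        XtViX += (Xg.T @ Xg - c * np.outer(x1, x1)) / s2e
        XtViy += (Xg.T @ yg - c * x1 * y1) / s2e
        ytViy += (yg @ yg - c * y1 * y1) / s2e
        logdet += (ng - 1) * np.log(s2e) + np.log(s2e + ng * s2u)
    return XtViX, XtViy, ytViy, logdet


def _profile_nll(theta, y, X, group_slices, reml):
    s2e, s2u = np.exp(np.clip(theta, _LOG_FLOOR, 15.0))
    XtViX, XtViy, ytViy, logdet = _gls_pieces(y, X, group_slices, s2e, s2u)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf
    quad = ytViy - beta @ XtViy  # residual quadratic form r' V^-1 r
    n = len(y)
    nll = 0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    if reml:
        sign, ld = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        nll += 0.5 * ld
    return nll


def fit_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                         reml: bool = True) -> RandomInterceptFit:
    """Fit the random-intercept model; raises :class:`EstimationError` on
    singular designs or failed optimization."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise EstimationError("singular fixed-effects design (e.g. a constant "
                              "covariate); cannot estimate the model")
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    uniq, starts = np.unique(groups, return_index=True)
    bounds = np.append(starts, n)
    group_slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(uniq))]

    # start from the OLS residual variance, split between the two components
    beta0, res0, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_tot = max(float(np.mean((y - X @ beta0) ** 2)), 1e-10)
    theta0 = np.log([0.8 * s2_tot, 0.2 * s2_tot])

    res = optimize.minimize(_profile_nll, theta0,
                            args=(y, X, group_slices, reml),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000})
    if not res.success:
        raise EstimationError(f"mixed-model optimization failed: {res.message}")
    theta = np.clip(res.x, _LOG_FLOOR, 15.0)
    boundary = bool(theta[1] <= _LOG_FLOOR + 1e-6)
    s2e, s2u = np.exp(theta)
    if boundary:
        s2u = 0.0
    XtViX, XtViy, _, _ = _gls_pieces(y, X, group_slices, s2e, max(s2u, 1e-300))
    cov = np.linalg.inv(XtViX)
    beta = cov @ XtViy
    return RandomInterceptFit(
        beta=beta, se=np.sqrt(np.diag(cov)), cov_beta=cov,
        sigma2_e=float(s2e), sigma2_u=float(s2u), loglik=float(-res.fun),
        df_resid=n - p, n_groups=len(uniq), boundary=boundary)
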