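"""Phenotypic selection gradients on floral traits, by sexual function.

Following the Lande–Arnold framework, relative fitness is regressed on
standardized traits (mean 0, sd 1): the linear coefficients are directional
selection gradients β, and twice the quadratic coefficients are the
stabilizing/disruptive gradients γ.  Sex-specific gradients come from a
bivariate model of the stacked female and male relative fitness of each
bisexual flower:

    w_{i,f} = Xβ_f + u_i + e_{i,f}

with a flower-level random intercept u_i (the two contributions of one
flower are not independent) and a separate residual variance for each sexual
function.  The model is fitted by direct numerical optimization of the
Gaussian (restricted) log-likelihood; because the per-flower covariance is a
common 2×2 matrix, the generalized least-squares step is a simple whitening.
Trait × function interactions are Wald contrasts β_f − β_m.

Two scalar indices summarize sexual antagonism per trait: SAS = |G_F − G_M|
(magnitude of divergence, always ≥ 0) and the signed, magnitude-scaled index
SA = G_F·G_M / sqrt((G_F² + G_M²)/2), negative exactly when the two
functions are selected in opposite directions.  Both are applied to linear
and to quadratic gradients.

Each trait × function is classified as under directional, stabilizing,
disruptive or no selection from the fitted quadratic fitness surface
restricted to the observed standardized trait range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import EstimationError
from .flowers import FlowerRecord

TRAITS = ["pistil_number", "stamen_number", "flowering_date",
          "tepal_length", "stalk_height"]

_LOG_FLOOR = -15.0


def trait_frame(flowers: Sequence[FlowerRecord]) -> pd.DataFrame:
    """Raw values of the five analysed floral traits, one row per flower.

    Stamen number is the effective (post-manipulation) count; flowering date
    is the integer opening day.
    """
    return pd.DataFrame({
        "flower_id": [f.flower_id for f in flowers],
        "pistil_number": [float(f.pistil_count) for f in flowers],
        "stamen_number": [float(f.stamen_count_effective) for f in flowers],
        "flowering_date": [float(f.opening_day) for f in flowers],
        "tepal_length": [float(f.tepal_length) for f in flowers],
        "stalk_height": [float(f.stalk_height) for f in flowers],
    }).set_index("flower_id")


@dataclass
class TraitMatrix:
    """Standardized traits (mean 0, sd 1) with back-transformation info."""
    z: pd.DataFrame               # standardized values, index = flower_id
    means: pd.Series
    sds: pd.Series

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)

    def z_range(self, trait: str) -> tuple[float, float]:
        col = self.z[trait]
        return float(col.min()), float(col.max())

    def back_transform(self, trait: str, z: np.ndarray | float):
        return self.means[trait] + self.sds[trait] * np.asarray(z, float)


def standardize(raw: pd.DataFrame,
                include_ids: Optional[Sequence[str]] = None) -> TraitMatrix:
    """Z-score each trait over the inclusion set.

    Uses the sample (ddof 1) standard deviation, the usual convention for
    selection-gradient analysis.  A zero-variance trait raises an error
    naming it.
    """
    df = raw.loc[list(include_ids)] if include_ids is not None else raw.copy()
    if len(df) < 3:
        raise EstimationError("need at least 3 flowers to standardize")
    means = df.mean()
    sds = df.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise EstimationError(f"trait {zero.index[0]!r} has zero variance")
    return TraitMatrix((df - means) / sds, means, sds)


# ---------------------------------------------------------------------------
# antagonism indices
# ---------------------------------------------------------------------------

def sas_index(G_F: float, G_M: float) -> float:
    """Absolute difference between female- and male-function gradients."""
    return abs(G_F - G_M)


def sa_index(G_F: float, G_M: float) -> float:
    """Signed antagonism index G_F·G_M / sqrt((G_F² + G_M²)/2).

    Negative iff selection acts in opposite directions on the two functions;
    bounded by the gradient magnitudes.  Defined as 0 (with a warning) when
    both gradients are zero.
    """
    if G_F == 0.0 and G_M == 0.0:
        warnings.warn("SA index undefined for two zero gradients; returning 0")
        return 0.0
    # factor out the larger magnitude so tiny gradients cannot underflow
    m = max(abs(G_F), abs(G_M))
    f, g = G_F / m, G_M / m
    return m * f * g / np.sqrt((f ** 2 + g ** 2) / 2.0)


# ---------------------------------------------------------------------------
# sex-specific gradients (bivariate heteroscedastic random-intercept model)
# ---------------------------------------------------------------------------

def _design(z: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Per-flower (2 × p) design blocks: row 0 = female, row 1 = male.

    Columns: function intercepts, then per trait the function-specific linear
    and quadratic regressors.
    """
    n = len(z)
    names = ["const_F", "const_M"]
    cols = [np.tile([1.0, 0.0], (n, 1)), np.tile([0.0, 1.0], (n, 1))]
    for t in z.columns:
        x = z[t].to_numpy()
        for vals, tag in ((x, "lin"), (x ** 2, "quad")):
            cols.append(np.column_stack([vals, np.zeros(n)]))
            names.append(f"{t}:{tag}_F")
            cols.append(np.column_stack([np.zeros(n), vals]))
            names.append(f"{t}:{tag}_M")
    X = np.stack(cols, axis=2)  # (n, 2, p)
    return X, names


def _whiten(theta, X, Y, reml):
    """Negative (restricted) log-likelihood for variance parameters theta =
    (log s2_F, log s2_M, log tau2), with fixed effects profiled out by GLS."""
    s2f, s2m, tau2 = np.exp(np.clip(theta, _LOG_FLOOR, 15.0))
    V = np.array([[s2f + tau2, tau2], [tau2, s2m + tau2]])
    try:
        C = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    Ci = np.linalg.inv(C)
    Xw = np.einsum("ab,nbp->nap", Ci, X).reshape(-1, X.shape[2])
    yw = (Y @ Ci.T).reshape(-1)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n, N = X.shape[0], 2 * X.shape[0]
    _, logdetV = np.linalg.slogdet(V)
    nll = 0.5 * (N * np.log(2 * np.pi) + n * logdetV + resid @ resid)
    if reml:
        sign, ld = np.linalg.slogdet(Xw.T @ Xw)
        if sign <= 0:
            return np.inf, None, None
        nll += 0.5 * ld
    return nll, beta, Xw


@dataclass
class SexSpecificFit:
    """Fitted bivariate selection-gradient model."""
    beta: np.ndarray
    cov_beta: np.ndarray
    names: list[str]
    sigma2_F: float
    sigma2_M: float
    tau2: float
    loglik: float
    n_flowers: int
    df_resid: int
    traits: list[str]
    trait_matrix: TraitMatrix = field(repr=False)
    boundary: bool = False

    def _idx(self, name: str) -> int:
        return self.names.index(name)

    def coef(self, name: str) -> tuple[float, float]:
        i = self._idx(name)
        return float(self.beta[i]), float(np.sqrt(self.cov_beta[i, i]))

    def _pvalue(self, est: float, se: float) -> float:
        return float(2 * stats.t.sf(abs(est) / se, self.df_resid))

    def contrast_p(self, name_f: str, name_m: str) -> float:
        i, j = self._idx(name_f), self._idx(name_m)
        diff = self.beta[i] - self.beta[j]
        var = (self.cov_beta[i, i] + self.cov_beta[j, j]
               - 2 * self.cov_beta[i, j])
        return float(2 * stats.t.sf(abs(diff) / np.sqrt(var), self.df_resid))

    def gradient_table(self) -> pd.DataFrame:
        """Per trait × term (beta, gamma): sex-specific estimates, SEs,
        interaction p-values, SAS and SA.  Quadratic regression coefficients
        are doubled to give γ."""
        rows = []
        for t in self.traits:
            for tag, term, scale in (("lin", "beta", 1.0), ("quad", "gamma", 2.0)):
                ef, sef = self.coef(f"{t}:{tag}_F")
                em, sem = self.coef(f"{t}:{tag}_M")
                ef, sef, em, sem = ef * scale, sef * scale, em * scale, sem * scale
                rows.append({
                    "trait": t, "term": term,
                    "est_F": ef, "se_F": sef, "p_F": self._pvalue(ef, sef),
                    "est_M": em, "se_M": sem, "p_M": self._pvalue(em, sem),
                    "p_interaction": self.contrast_p(f"{t}:{tag}_F",
                                                     f"{t}:{tag}_M"),
                    "SAS": sas_index(ef, em),
                    "SA": sa_index(ef, em),
                })
        return pd.DataFrame(rows)


def fit_sex_specific(traits: TraitMatrix, fitness: pd.DataFrame,
                     reml: bool = True) -> SexSpecificFit:
    """Fit the stacked female/male relative-fitness model.

    ``fitness`` must carry ``flower_id``, ``relW_female`` and ``relW_male``
    for every flower in the trait matrix.  Raises on non-convergence; a
    random-intercept variance driven to zero is reported as a boundary fit
    with a warning, not an error.
    """
    fit_df = fitness.set_index("flower_id").loc[traits.z.index]
    Y = fit_df[["relW_female", "relW_male"]].to_numpy(float)
    X, names = _design(traits.z)
    n, p = X.shape[0], X.shape[2]
    if 2 * n <= p:
        raise EstimationError("more parameters than observations")
    Xflat = X.reshape(-1, p)
    if np.linalg.matrix_rank(Xflat) < p:
        raise EstimationError("rank-deficient design matrix")

    # start at the per-function OLS residual covariance (with identical
    # regressors in both equations, GLS fixed effects equal equation-wise
    # OLS, so this start is essentially the optimum already)
    Zcols = [np.ones(n)]
    for t in traits.traits:
        x = traits.z[t].to_numpy()
        Zcols += [x, x ** 2]
    Z1 = np.column_stack(Zcols)
    resF = Y[:, 0] - Z1 @ np.linalg.lstsq(Z1, Y[:, 0], rcond=None)[0]
    resM = Y[:, 1] - Z1 @ np.linalg.lstsq(Z1, Y[:, 1], rcond=None)[0]
    dd = max(n - Z1.shape[1], 1)
    vF, vM = resF @ resF / dd, resM @ resM / dd
    cFM = resF @ resM / dd
    tau0 = min(max(cFM, 1e-3 * np.sqrt(vF * vM)), 0.9 * min(vF, vM))
    theta0 = np.log([max(vF - tau0, 1e-6), max(vM - tau0, 1e-6), tau0])

    res = optimize.minimize(lambda th: _whiten(th, X, Y, reml)[0], theta0,
                            method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-11,
                                     "maxiter": 6000})
    if not res.success:
        raise EstimationError(f"selection-model optimization failed: {res.message}")
    theta = np.clip(res.x, _LOG_FLOOR, 15.0)
    boundary = bool(np.any(theta <= _LOG_FLOOR + 1e-6))
    if boundary:
        warnings.warn("a variance component was driven to its boundary (~0); "
                      "refit at the boundary value")
    nll, beta, Xw = _whiten(theta, X, Y, reml)
    cov = np.linalg.inv(Xw.T @ Xw)
    s2f, s2m, tau2 = np.exp(theta)
    return SexSpecificFit(
        beta=beta, cov_beta=cov, names=names,
        sigma2_F=float(s2f), sigma2_M=float(s2m), tau2=float(tau2),
        loglik=float(-nll), n_flowers=n, df_resid=2 * n - p,
        traits=traits.traits, trait_matrix=traits, boundary=boundary)


def marginal_covariance(fit: SexSpecificFit) -> np.ndarray:
    """The fitted 2×2 per-flower covariance of (female, male) fitness."""
    return np.array([[fit.sigma2_F + fit.tau2, fit.tau2],
                     [fit.tau2, fit.sigma2_M + fit.tau2]])


# ---------------------------------------------------------------------------
# combined (summed) fitness
# ---------------------------------------------------------------------------

def fit_combined(traits: TraitMatrix, combined_w: pd.Series) -> pd.DataFrame:
    """OLS of combined relative fitness (relW_female + relW_male) on linear
    and quadratic trait terms; quadratic coefficients doubled to γ."""
    y = combined_w.loc[traits.z.index].to_numpy(float)
    cols, names = [np.ones(len(y))], ["const"]
    for t in traits.traits:
        x = traits.z[t].to_numpy()
        cols += [x, x ** 2]
        names += [f"{t}:lin", f"{t}:quad"]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("rank-deficient combined-model design")
    ols = sm.OLS(y, X).fit()
    rows = []
    for t in traits.traits:
        for tag, term, scale in (("lin", "beta", 1.0), ("quad", "gamma", 2.0)):
            i = names.index(f"{t}:{tag}")
            rows.append({"trait": t, "term": term,
                         "est": float(ols.params[i]) * scale,
                         "se": float(ols.bse[i]) * scale,
                         "p": float(ols.pvalues[i])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# selection-regime classification
# ---------------------------------------------------------------------------

@dataclass
class Regime:
    label: str                 # directional | stabilizing | disruptive | none
    optimum: Optional[float]   # argmax of the fitted surface on the z range


def classify_regime(beta: float, gamma: float, p_beta: float, p_gamma: float,
                    z_range: tuple[float, float],
                    alpha: float = 0.05) -> Regime:
    """Classify the selection regime from the quadratic fitness surface
    w(z) = βz + (γ/2)z² restricted to the observed standardized range.

    Neither term significant → ``none``.  A significant quadratic term with
    an interior stationary point gives ``stabilizing`` (γ < 0, the optimum)
    or ``disruptive`` (γ > 0, an interior minimum with fitness maximized at a
    range endpoint); otherwise selection is ``directional`` toward the
    endpoint with higher fitted fitness.
    """
    z_min, z_max = z_range
    if z_min >= z_max:
        raise ValueError("empty trait range")
    sig_b, sig_g = p_beta < alpha, p_gamma < alpha
    if not sig_b and not sig_g:
        return Regime("none", None)
    if beta == 0.0 and gamma == 0.0:
        raise EstimationError("zero gradients flagged significant: "
                              "inconsistent inputs")

    g_active = gamma if sig_g else 0.0

    def w(z):
        return beta * z + 0.5 * g_active * z ** 2

    if g_active != 0.0:
        z_star = -beta / g_active
        if z_min < z_star < z_max:
            if g_active < 0:
                return Regime("stabilizing", float(z_star))
            best = z_min if w(z_min) >= w(z_max) else z_max
            return Regime("disruptive", float(best))
    best = z_min if w(z_min) >= w(z_max) else z_max
    return Regime("directional", float(best))


def regime_table(gradients: pd.DataFrame, traits: TraitMatrix,
                 functions: Sequence[str] = ("F", "M"),
                 alpha: float = 0.05) -> pd.DataFrame:
    """Regime labels per trait for each sexual function from a sex-specific
    gradient table (as produced by :meth:`SexSpecificFit.gradient_table`)."""
    rows = []
    for t in traits.traits:
        sub = gradients[gradients["trait"] == t].set_index("term")
        rng = traits.z_range(t)
        row = {"trait": t}
        for fn in functions:
            reg = classify_regime(
                beta=float(sub.loc["beta", f"est_{fn}"]),
                gamma=float(sub.loc["gamma", f"est_{fn}"]),
                p_beta=float(sub.loc["beta", f"p_{fn}"]),
                p_gamma=float(sub.loc["gamma", f"p_{fn}"]),
                z_range=rng, alpha=alpha)
            row[f"regime_{fn}"] = reg.label
            row[f"optimum_{fn}"] = reg.optimum
        rows.append(row)
    return pd.DataFrame(rows)


def combined_regime_table(combined: pd.DataFrame, traits: TraitMatrix,
                          alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for t in traits.traits:
        sub = combined[combined["trait"] == t].set_index("term")
        reg = classify_regime(
            beta=float(sub.loc["beta", "est"]),
            gamma=float(sub.loc["gamma", "est"]),
            p_beta=float(sub.loc["beta", "p"]),
            p_gamma=float(sub.loc["gamma", "p"]),
            z_range=traits.z_range(t), alpha=alpha)
        rows.append({"trait": t, "regime": reg.label, "optimum": reg.optimum})
    return pd.DataFrame(rows)
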