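"""Linear mixed models with crossed random intercepts and Satterthwaite df.

Group comparisons use models of the form

    y = X beta + sum_k  u_k  (random intercepts for factor k) + e,

with u_k ~ N(0, s2_k I) for crossed factors such as scan site and gene, and
e ~ N(0, s2_e I).  Estimation is by REML through statsmodels MixedLM (variance
components formulation on a single all-encompassing group).  Factors with
fewer than two observed levels carry no information about their variance and
are dropped with a warning; with no random factors left the model reduces to
ordinary least squares.

statsmodels does not provide Satterthwaite degrees of freedom, so they are
computed here from first principles: for a contrast c the effective df is

    df = 2 f(th)^2 / (grad f' Sigma_th grad f),     f(th) = c' (X' V^-1 X)^-1 c,

with th the variance parameters (s2_1..s2_K, s2_e), grad f by central finite
differences, and Sigma_th the inverse observed information of the REML
log-likelihood (numerical Hessian).  Variance components estimated at the
zero boundary are held fixed.  The implementation is validated against R's
lmerTest in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "LmmFit",
    "fit_variance_components",
    "satterthwaite_contrast",
    "satterthwaite_joint",
]


def _one_hot(values) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(values))
    z = np.zeros((len(codes), codes.max() + 1))
    z[np.arange(len(codes)), codes] = 1.0
    return z


@dataclass
class LmmFit:
    """A fitted variance-components model plus everything Satterthwaite needs."""

    params: pd.Series
    cov_params: pd.DataFrame
    vcomp: dict  # factor name -> variance
    sigma2: float
    loglike_reml: float
    loglike_ml: float
    n_obs: int
    method: str  # "reml-vc" or "ols"
    dropped_factors: list = field(default_factory=list)
    y: np.ndarray | None = None
    X: np.ndarray | None = None
    Z: dict | None = None  # factor name -> indicator matrix
    converged: bool = True

    @property
    def df_resid_ols(self) -> float:
        return self.n_obs - self.X.shape[1]


def _reml_loglike(y, X, Z_list, theta):
    """REML log-likelihood at variance parameters theta = (s2_1..s2_K, s2_e)."""
    n, p = X.shape
    s2e = theta[-1]
    V = s2e * np.eye(n)
    for Z, s2 in zip(Z_list, theta[:-1]):
        V += s2 * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = X.T @ Vi_X
    sign, logdetXVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = r @ np.linalg.solve(V, r)
    return -0.5 * (logdetV + logdetXVX + quad + (n - p) * np.log(2 * np.pi))


def _contrast_variance(X, Z_list, theta, c):
    n = X.shape[0]
    V = theta[-1] * np.eye(n)
    for Z, s2 in zip(Z_list, theta[:-1]):
        V += s2 * (Z @ Z.T)
    XtViX = X.T @ np.linalg.solve(V, X)
    return float(c @ np.linalg.solve(XtViX, c))


def fit_variance_components(
    y: np.ndarray,
    X: pd.DataFrame,
    factors: dict,
    reml: bool = True,
) -> LmmFit:
    """Fit y ~ X with crossed random intercepts for each factor.

    ``factors`` maps a name to a vector of level labels (one per row).
    Factors with < 2 observed levels are dropped with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    Xmat = np.asarray(X, dtype=float)
    names = list(X.columns)
    usable, dropped = {}, []
    for name, vals in factors.items():
        if pd.Series(list(vals)).nunique() >= 2:
            usable[name] = np.asarray(vals)
        else:
            dropped.append(name)
            logger.warning("random factor %r has < 2 levels; dropped from the model", name)

    if not usable:
        ols = sm.OLS(y, Xmat).fit()
        olsm = sm.OLS(y, Xmat)
        return LmmFit(
            params=pd.Series(ols.params, index=names),
            cov_params=pd.DataFrame(ols.cov_params(), index=names, columns=names),
            vcomp={},
            sigma2=float(ols.mse_resid),
            loglike_reml=float(ols.llf),
            loglike_ml=float(olsm.loglike(ols.params)),
            n_obs=len(y),
            method="ols",
            dropped_factors=dropped,
            y=y,
            X=Xmat,
            Z={},
        )

    df = pd.DataFrame(Xmat, columns=names)
    df["_y"] = y
    vc_formula = {}
    for name, vals in usable.items():
        df[f"_f_{name}"] = pd.Categorical(vals)
        vc_formula[name] = f"0 + C(_f_{name})"
    df["_g"] = 1
    fixed = "_y ~ 0 + " + " + ".join(f"Q('{c}')" for c in names)
    model = sm.MixedLM.from_formula(
        fixed, groups="_g", vc_formula=vc_formula, re_formula="0", data=df
    )
    converged = True
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=200)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = model.fit(reml=reml, method="powell", maxiter=500)
            converged = False

    # statsmodels orders variance components by its own internal naming
    vc_order = list(getattr(model.exog_vc, "names", sorted(vc_formula)))
    vcomp_by_name = {name: max(float(v), 0.0) for name, v in zip(vc_order, res.vcomp)}
    vcomp = {name: vcomp_by_name[name] for name in usable}
    params = pd.Series(np.asarray(res.fe_params), index=names)
    covp = pd.DataFrame(np.asarray(res.cov_params())[: len(names), : len(names)],
                        index=names, columns=names)
    Z = {name: _one_hot(vals) for name, vals in usable.items()}
    theta = np.array([vcomp[k] for k in Z] + [float(res.scale)])
    ll_reml = _reml_loglike(y, Xmat, list(Z.values()), theta) if reml else np.nan
    return LmmFit(
        params=params,
        cov_params=covp,
        vcomp=vcomp,
        sigma2=float(res.scale),
        loglike_reml=float(ll_reml) if reml else float("nan"),
        loglike_ml=float(res.llf) if not reml else float("nan"),
        n_obs=len(y),
        method="reml-vc",
        dropped_factors=dropped,
        y=y,
        X=Xmat,
        Z=Z,
        converged=converged,
    )


def satterthwaite_contrast(fit: LmmFit, c: np.ndarray):
    """Estimate, SE, Satterthwaite df, t and p for the contrast c' beta."""
    from scipy import stats

    c = np.asarray(c, dtype=float)
    est = float(c @ fit.params.to_numpy())
    if fit.method == "ols":
        var = float(c @ fit.cov_params.to_numpy() @ c)
        df = fit.df_resid_ols
        t = est / np.sqrt(var) if var > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df) if var > 0 else np.nan
        return est, float(np.sqrt(var)), float(df), float(t), float(p)

    Z_list = list(fit.Z.values())
    theta = np.array(list(fit.vcomp.values()) + [fit.sigma2])
    var_y = np.var(fit.y)
    free = [k for k, th in enumerate(theta) if th > 1e-8 * var_y or k == len(theta) - 1]

    f0 = _contrast_variance(fit.X, Z_list, theta, c)

    # gradient of the contrast variance w.r.t. the free variance parameters
    # keep the residual variance strictly positive during differencing so V
    # stays invertible even for (near-)noiseless data
    floor = max(1e-10 * max(var_y, 1.0), 1e-300)
    grad = np.zeros(len(free))
    for gi, k in enumerate(free):
        h = max(1e-7 * var_y, 1e-4 * theta[k])
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] = max(tm[k] - h, floor if k == len(theta) - 1 else 0.0)
        fp = _contrast_variance(fit.X, Z_list, tp, c)
        fm = _contrast_variance(fit.X, Z_list, tm, c)
        grad[gi] = (fp - fm) / (tp[k] - tm[k])

    # observed information of the REML log-likelihood (numerical Hessian)
    def ll(th_free):
        th = theta.copy()
        th[free] = th_free
        if np.any(th < 0):
            return -np.inf
        th[-1] = max(th[-1], floor)
        return _reml_loglike(fit.y, fit.X, Z_list, th)

    th0 = theta[free]
    k = len(th0)
    H = np.zeros((k, k))
    hs = np.maximum(1e-6 * var_y, 1e-3 * th0)
    l0 = ll(th0)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp, tm = th0.copy(), th0.copy()
                tp[i] += hs[i]
                tm[i] -= hs[i]
                if tm[i] < 0:
                    tm[i] = 0.0
                num = ll(tp) - 2 * l0 + ll(tm)
                H[i, i] = num / ((tp[i] - th0[i]) * (th0[i] - tm[i]) or hs[i] ** 2)
            else:
                tpp, tpm, tmp, tmm = (th0.copy() for _ in range(4))
                tpp[[i, j]] += hs[[i, j]]
                tpm[i] += hs[i]
                tpm[j] = max(tpm[j] - hs[j], 0.0)
                tmp[j] += hs[j]
                tmp[i] = max(tmp[i] - hs[i], 0.0)
                tmm[i] = max(tmm[i] - hs[i], 0.0)
                tmm[j] = max(tmm[j] - hs[j], 0.0)
                H[i, j] = H[j, i] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (
                    (tpp[i] - tmm[i]) * (tpp[j] - tmm[j])
                )

    from scipy import stats

    df_resid = fit.n_obs - fit.X.shape[1]
    try:
        cov_theta = np.linalg.inv(-H)
        denom = float(grad @ cov_theta @ grad)
        df = 2.0 * f0**2 / denom if denom > 0 else df_resid
    except np.linalg.LinAlgError:
        df = df_resid
    if not np.isfinite(df) or df <= 0:
        df = df_resid
    df = float(np.clip(df, 1.0, df_resid))
    se = float(np.sqrt(f0))
    t = est / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df)
    return est, se, df, float(t), float(p)


def satterthwaite_joint(fit: LmmFit, C: np.ndarray):
    """Joint Wald F test of the rows of C with Satterthwaite denominator df.

    F = (C b)' [C Cov(b) C']^{-1} (C b) / q, with the denominator df taken as
    the mean of the per-row Satterthwaite dfs (the rows here are individual
    model terms).  In the OLS path Cov(b) is exact and the test coincides
    with the exact nested F test.
    """
    from scipy import stats

    C = np.atleast_2d(np.asarray(C, dtype=float))
    q = C.shape[0]
    b = fit.params.to_numpy()
    if fit.method == "ols":
        covb = fit.cov_params.to_numpy()
        df2 = fit.df_resid_ols
    else:
        Z_list = list(fit.Z.values())
        theta = np.array(list(fit.vcomp.values()) + [fit.sigma2])
        n = fit.X.shape[0]
        V = theta[-1] * np.eye(n)
        for Z, s2 in zip(Z_list, theta[:-1]):
            V += s2 * (Z @ Z.T)
        covb = np.linalg.inv(fit.X.T @ np.linalg.solve(V, fit.X))
        df2 = float(np.mean([satterthwaite_contrast(fit, c)[2] for c in C]))
    Cb = C @ b
    M = C @ covb @ C.T
    fstat = float(Cb @ np.linalg.solve(M, Cb)) / q
    p = float(stats.f.sf(fstat, q, df2))
    return fstat, q, float(df2), p
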