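"""Two-level random-intercept models of remittance with sampling weights.

Two families are implemented:

* a mixed-effects logistic model for whether a migrant sends remittance,
  fit by maximising the weighted marginal likelihood with adaptive
  Gauss–Hermite quadrature over the group intercept (Laplace mode/curvature
  centring, 15 nodes by default);
* a mixed-effects linear model for log10 remittance amount among senders,
  fit by ML (or REML) on the marginal Gaussian likelihood with the fixed
  effects profiled out in closed form via the Woodbury identity.

Sampling weights enter both likelihoods as observation-level pseudo-
likelihood weights. The intraclass correlation uses the logistic residual
variance π²/3 for the logit family and σ_τ² for the linear family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import logsumexp

LOGISTIC_RESIDUAL_VAR = np.pi**2 / 3


class SeparationError(ValueError):
    """The binary response is (quasi-)separated; the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """An optimiser failed where a flagged fit is not acceptable."""


@dataclass
class MixedModelFit:
    """A fitted two-level random-intercept model."""

    family: str  # "logit" | "linear"
    response: str
    columns: list[str]  # fixed-effect design columns (incl. "const")
    params: pd.Series
    se: pd.Series
    sigma_u: float  # random-intercept s.d.
    sigma_e: float  # residual s.d. (linear) or sqrt(pi^2/3) (logit)
    icc: float
    loglik: float
    n: int
    k: int  # estimated parameters
    converged: bool
    group: str
    method: str = "ML"
    singleton_groups: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None  # cov of (beta, log sigma_u) or (beta,)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.se})

    def to_jsonable(self) -> dict:
        return {
            "family": self.family,
            "response": self.response,
            "coef": self.params.to_dict(),
            "se": self.se.to_dict(),
            "sigma_u": self.sigma_u,
            "sigma_e": self.sigma_e,
            "icc": self.icc,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _design(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str,
    weights: str | None,
):
    missing = [c for c in [response, *fixed, group] if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    df = data.dropna(subset=[response, *fixed, group]).copy()
    y = df[response].to_numpy(float)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in fixed])
    cols = ["const", *fixed]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effect design (collinear columns)")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    codes, uniques = pd.factorize(df[group], sort=True)
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    w = (
        df[weights].to_numpy(float)[order]
        if weights is not None
        else np.ones(len(df))
    )
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    # pseudo-likelihood scaling: normalise to mean 1 so the information
    # matches the sample size and a uniform rescaling leaves the fit alone
    w = w / w.mean()
    sizes = np.bincount(codes)
    singles = [str(uniques[i]) for i in np.flatnonzero(sizes == 1)]
    if singles:
        warnings.warn(
            f"{len(singles)} group(s) of size 1 (e.g. {singles[:5]}); "
            "they contribute through the marginal integral"
        )
    if len(uniques) < 2:
        raise ValueError("grouping must have at least 2 groups")
    return y, X, cols, codes, len(uniques), w, singles


def _num_hessian(fun, x, step=1e-4):
    x = np.asarray(x, float)
    p = len(x)
    H = np.zeros((p, p))
    hs = step * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = hs[i]
            ej[j] = hs[j]
            f = (
                fun(x + ei + ej)
                - fun(x + ei - ej)
                - fun(x - ei + ej)
                + fun(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
            H[i, j] = H[j, i] = f
    return H


# ---------------------------------------------------------------------------
# mixed logistic
# ---------------------------------------------------------------------------

def _logit_group_loglik(y, X, codes, C, w, beta, sigma, nodes, wts):
    """Per-group marginal log-likelihood by adaptive Gauss-Hermite."""
    eta0 = X @ beta
    wy = w * y
    # Newton to the per-group posterior mode of the intercept
    u = np.zeros(C)
    for _ in range(50):
        eta = eta0 + u[codes]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(codes, weights=w * (y - p), minlength=C) - u / sigma**2
        hess = (
            np.bincount(codes, weights=w * p * (1 - p), minlength=C)
            + 1.0 / sigma**2
        )
        step = grad / hess
        step = np.clip(step, -5.0, 5.0)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[codes]
    p = 1.0 / (1.0 + np.exp(-eta))
    H = (
        np.bincount(codes, weights=w * p * (1 - p), minlength=C)
        + 1.0 / sigma**2
    )
    scale = np.sqrt(2.0 / H)  # (C,)
    # log integrand at shifted nodes, for each quadrature point
    terms = np.empty((len(nodes), C))
    for q, (xq, wq) in enumerate(zip(nodes, wts)):
        uq = u + scale * xq
        etaq = eta0 + uq[codes]
        ll_obs = wy * etaq - w * np.logaddexp(0.0, etaq)
        ll_g = np.bincount(codes, weights=ll_obs, minlength=C)
        ll_g += -0.5 * uq**2 / sigma**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        terms[q] = np.log(wq) + xq**2 + ll_g
    return logsumexp(terms, axis=0) + np.log(scale)


def fit_mixed_logit(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str,
    weights: str | None = None,
    n_quad: int = 15,
    fix_sigma_u: float | None = None,
) -> MixedModelFit:
    """Weighted random-intercept logistic regression.

    ``fix_sigma_u=0`` constrains the group variance to zero, reducing the
    model to a plain weighted logistic fit (used for oracle checks).
    Non-convergence yields a flagged fit; separation raises
    :class:`SeparationError`.
    """
    y, X, cols, codes, C, w, singles = _design(
        data, response, fixed, group, weights
    )
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("response is constant; model is separated")
    nodes, wts = hermgauss(n_quad)
    p_fix = X.shape[1]

    if fix_sigma_u is not None and fix_sigma_u == 0.0:
        def nll(beta):
            eta = X @ beta
            return -np.sum(w * (y * eta - np.logaddexp(0.0, eta)))

        x0 = np.zeros(p_fix)
        x0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
        res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-8})
        beta = res.x
        if np.max(np.abs(beta)) > 30:
            raise SeparationError("coefficients diverge: separation suspected")
        H = _num_hessian(nll, beta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        # scaled-gradient test: BFGS can stop on float precision with the
        # solution long converged relative to the log-likelihood magnitude
        grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-5 * (
            1.0 + abs(float(res.fun))
        )
        return MixedModelFit(
            family="logit",
            response=response,
            columns=cols,
            params=pd.Series(beta, index=cols),
            se=pd.Series(se, index=cols),
            sigma_u=0.0,
            sigma_e=float(np.sqrt(LOGISTIC_RESIDUAL_VAR)),
            icc=0.0,
            loglik=float(-res.fun),
            n=len(y),
            k=p_fix,
            converged=bool(res.success or grad_ok),
            group=group,
            singleton_groups=singles,
            cov=cov,
        )

    def nll(theta):
        beta, log_sigma = theta[:p_fix], theta[p_fix]
        sigma = np.exp(log_sigma)
        return -np.sum(_logit_group_loglik(y, X, codes, C, w, beta, sigma, nodes, wts))

    x0 = np.zeros(p_fix + 1)
    x0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
    x0[-1] = np.log(0.3 if fix_sigma_u is None else fix_sigma_u)
    bounds = [(-30, 30)] * p_fix + [(-6, 3)]
    if fix_sigma_u is not None:
        lv = float(np.log(fix_sigma_u))
        bounds[-1] = (lv, lv)
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    beta, sigma_u = res.x[:p_fix], float(np.exp(res.x[p_fix]))
    if np.max(np.abs(beta)) >= 29.5:
        raise SeparationError("coefficients diverge: separation suspected")

    free = p_fix if fix_sigma_u is not None else p_fix + 1
    H = _num_hessian(lambda t: nll(np.append(t, res.x[p_fix])) if free == p_fix else nll(t),
                     res.x[:free])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
        ok = bool(res.success)
    except np.linalg.LinAlgError:
        cov = np.full((free, free), np.nan)
        se_all = np.full(free, np.nan)
        ok = False
    icc = sigma_u**2 / (sigma_u**2 + LOGISTIC_RESIDUAL_VAR)
    return MixedModelFit(
        family="logit",
        response=response,
        columns=cols,
        params=pd.Series(beta, index=cols),
        se=pd.Series(se_all[:p_fix], index=cols),
        sigma_u=sigma_u,
        sigma_e=float(np.sqrt(LOGISTIC_RESIDUAL_VAR)),
        icc=float(icc),
        loglik=float(-res.fun),
        n=len(y),
        k=p_fix + (0 if fix_sigma_u is not None else 1),
        converged=ok,
        group=group,
        singleton_groups=singles,
        cov=cov,
    )


# ---------------------------------------------------------------------------
# mixed linear
# ---------------------------------------------------------------------------

def _linear_profile(y, X, codes, C, w, var_u, var_e, reml):
    """Profiled marginal Gaussian (restricted) log-likelihood pieces."""
    a = w / var_e  # per-observation precision
    s = np.bincount(codes, weights=a, minlength=C)
    c = var_u / (1.0 + var_u * s)  # Woodbury correction per group

    aX = X * a[:, None]
    gX = np.stack(
        [np.bincount(codes, weights=aX[:, j], minlength=C) for j in range(X.shape[1])],
        axis=1,
    )  # (C, p) group sums of a*x
    XtVX = X.T @ aX - gX.T @ (gX * c[:, None])
    ay = a * y
    gy = np.bincount(codes, weights=ay, minlength=C)
    XtVy = X.T @ ay - gX.T @ (c * gy)
    beta = np.linalg.solve(XtVX, XtVy)

    r = y - X @ beta
    ar = a * r
    gr = np.bincount(codes, weights=ar, minlength=C)
    quad = float(r @ ar - gr @ (c * gr))
    logdet = float(np.sum(np.log(var_e / w)) + np.sum(np.log1p(var_u * s)))
    n = len(y)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        ll -= 0.5 * ld
    return ll, beta, XtVX


def fit_mixed_linear(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str,
    weights: str | None = None,
    reml: bool = False,
    fix_sigma_u: float | None = None,
) -> MixedModelFit:
    """Weighted random-intercept linear regression (ML by default).

    ``fix_sigma_u=0`` reduces the model to weighted least squares.
    """
    y, X, cols, codes, C, w, singles = _design(
        data, response, fixed, group, weights
    )
    p_fix = X.shape[1]

    if fix_sigma_u is not None and fix_sigma_u == 0.0:
        WX = X * w[:, None]
        XtWX = X.T @ WX
        beta = np.linalg.solve(XtWX, X.T @ (w * y))
        r = y - X @ beta
        var_e = float(np.sum(w * r * r) / len(y))  # ML estimate
        ll, _, XtVX = _linear_profile(
            y, X, codes, C, w, 0.0, var_e, reml=False
        )
        cov = np.linalg.inv(XtVX)
        return MixedModelFit(
            family="linear",
            response=response,
            columns=cols,
            params=pd.Series(beta, index=cols),
            se=pd.Series(np.sqrt(np.diag(cov)), index=cols),
            sigma_u=0.0,
            sigma_e=float(np.sqrt(var_e)),
            icc=0.0,
            loglik=float(ll),
            n=len(y),
            k=p_fix + 1,
            converged=True,
            group=group,
            singleton_groups=singles,
            cov=cov,
        )

    # initial residual variance from the WLS fit
    beta0 = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
    var0 = float(np.sum(w * (y - X @ beta0) ** 2) / len(y))

    def nll(theta):
        var_u, var_e = np.exp(theta)
        ll, _, _ = _linear_profile(y, X, codes, C, w, var_u, var_e, reml)
        return -ll

    if fix_sigma_u is not None:
        lv = 2 * np.log(fix_sigma_u)
        res = optimize.minimize_scalar(
            lambda t: nll(np.array([lv, t])),
            bounds=(np.log(var0) - 8, np.log(var0) + 4),
            method="bounded",
        )
        theta = np.array([lv, res.x])
        success = True
    else:
        res = optimize.minimize(
            nll,
            np.log([0.2 * var0 + 1e-8, 0.8 * var0 + 1e-8]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        theta = res.x
        success = bool(res.success)

    var_u, var_e = np.exp(theta)
    ll, beta, XtVX = _linear_profile(y, X, codes, C, w, var_u, var_e, reml)
    cov = np.linalg.inv(XtVX)
    icc = var_u / (var_u + var_e)
    return MixedModelFit(
        family="linear",
        response=response,
        columns=cols,
        params=pd.Series(beta, index=cols),
        se=pd.Series(np.sqrt(np.diag(cov)), index=cols),
        sigma_u=float(np.sqrt(var_u)),
        sigma_e=float(np.sqrt(var_e)),
        icc=float(icc),
        loglik=float(ll),
        n=len(y),
        k=p_fix + (1 if fix_sigma_u is not None else 2),
        converged=success,
        group=group,
        method="REML" if reml else "ML",
        singleton_groups=singles,
        cov=cov,
    )


# ---------------------------------------------------------------------------
# marginal effects and predictive margins
# ---------------------------------------------------------------------------

def _pa_probability(fit: MixedModelFit, x: np.ndarray, n_quad: int = 41):
    """Population-averaged P(y=1|x), integrating the group intercept out."""
    nodes, wts = hermgauss(n_quad)
    eta = float(x @ fit.params.to_numpy())
    z = eta + np.sqrt(2.0) * fit.sigma_u * nodes
    p = 1.0 / (1.0 + np.exp(-z))
    return float(np.sum(wts * p) / np.sqrt(np.pi)), float(
        np.sum(wts * p * (1 - p)) / np.sqrt(np.pi)
    )


@dataclass
class MarginalEffects:
    effects: pd.DataFrame  # variable, effect, se
    at: pd.Series
    margins: pd.DataFrame | None = None  # predictive margins over a grid


def marginal_effects(
    fit: MixedModelFit,
    at: dict | pd.Series,
    variables: list[str] | None = None,
    grid_var: str | None = None,
    grid: np.ndarray | None = None,
) -> MarginalEffects:
    """Marginal effects at a covariate point, plus optional margins grid.

    Logistic family: dP/dx_j = β_j · E_u[P(1-P)] with the expectation over
    the random intercept taken by Gauss–Hermite quadrature. Linear family:
    the effect is the coefficient itself. ``grid_var``/``grid`` add
    predictive margins over a grid of one covariate (e.g. a 0→12,000 Yuan
    payment sweep).
    """
    if not fit.converged:
        raise ConvergenceError("marginal effects require a converged fit")
    at = pd.Series(at, dtype=float)
    missing = [c for c in fit.columns if c != "const" and c not in at.index]
    if missing:
        raise KeyError(f"'at' is missing model columns: {missing}")
    x = np.array(
        [1.0] + [float(at[c]) for c in fit.columns if c != "const"]
    )
    names = [c for c in fit.columns if c != "const"]
    if variables is None:
        variables = names

    rows = []
    if fit.family == "linear":
        for v in variables:
            rows.append(
                {"variable": v, "effect": fit.params[v], "se": fit.se[v]}
            )
    else:
        nodes, wts = hermgauss(41)
        p_fix = len(fit.columns)
        # free parameters match fit.cov: (beta,) or (beta, log sigma_u)
        nfree = fit.cov.shape[0] if fit.cov is not None else p_fix
        theta = fit.params.to_numpy()
        if nfree > p_fix:
            theta = np.append(theta, np.log(max(fit.sigma_u, 1e-8)))

        def me_of(theta_vec, j):
            beta = theta_vec[:p_fix]
            sigma = np.exp(theta_vec[p_fix]) if nfree > p_fix else fit.sigma_u
            z = float(x @ beta) + np.sqrt(2.0) * sigma * nodes
            p = 1.0 / (1.0 + np.exp(-z))
            return theta_vec[j] * float(np.sum(wts * p * (1 - p)) / np.sqrt(np.pi))

        _, slope_factor = _pa_probability(fit, x)
        for v in variables:
            j = fit.columns.index(v)
            effect = fit.params[v] * slope_factor
            if fit.cov is not None and np.all(np.isfinite(fit.cov)):
                g = np.zeros(nfree)
                for i in range(nfree):
                    h = 1e-5 * max(1.0, abs(theta[i]))
                    tp, tm = theta.copy(), theta.copy()
                    tp[i] += h
                    tm[i] -= h
                    g[i] = (me_of(tp, j) - me_of(tm, j)) / (2 * h)
                se = float(np.sqrt(max(g @ fit.cov @ g, 0.0)))
            else:
                se = np.nan
            rows.append({"variable": v, "effect": effect, "se": se})

    margins = None
    if grid_var is not None:
        if grid is None:
            raise ValueError("grid required with grid_var")
        j = fit.columns.index(grid_var)
        mrows = []
        for v in np.asarray(grid, float):
            xv = x.copy()
            xv[j] = v
            if fit.family == "linear":
                mrows.append({grid_var: v, "margin": float(xv @ fit.params.to_numpy())})
            else:
                pbar, _ = _pa_probability(fit, xv)
                mrows.append({grid_var: v, "margin": pbar})
        margins = pd.DataFrame(mrows)
    return MarginalEffects(
        effects=pd.DataFrame(rows), at=at, margins=margins
    )


# ---------------------------------------------------------------------------
# weighted bootstrap of the marginal-effect distribution
# ---------------------------------------------------------------------------

def bootstrap_margin_distribution(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str,
    focal: str,
    weights: str | None = None,
    cluster: str = "household_id",
    family: str = "logit",
    n_reps: int = 200,
    seed: int = 0,
    **fit_kwargs,
) -> dict:
    """Weighted-bootstrap distribution of the focal marginal effect.

    Households (clusters) are resampled with replacement with probability
    proportional to their sampling weight; the model is refit on each
    replicate and the marginal effect of ``focal`` evaluated at the
    original covariate means. Raises if n_reps < 100 or if more than 20% of
    replicates fail to converge.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    rng = np.random.default_rng(seed)
    fit_fun = fit_mixed_logit if family == "logit" else fit_mixed_linear
    clusters = data[cluster].drop_duplicates().to_numpy()
    if weights is not None:
        wc = data.groupby(cluster)[weights].first().reindex(clusters).to_numpy()
        prob = wc / wc.sum()
    else:
        prob = None
    at = data[fixed].mean()
    by_cluster = {c: sub for c, sub in data.groupby(cluster)}

    samples = []
    failures = 0
    for _ in range(n_reps):
        draw = rng.choice(clusters, size=len(clusters), replace=True, p=prob)
        boot = pd.concat([by_cluster[c] for c in draw], ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fit_fun(
                    boot, response, fixed, group, weights=weights, **fit_kwargs
                )
            me = marginal_effects(f, at, variables=[focal])
            samples.append(float(me.effects["effect"].iloc[0]))
        except (SeparationError, ConvergenceError, ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.2 * n_reps:
        raise ConvergenceError(
            f"{failures}/{n_reps} bootstrap replicates failed to converge"
        )
    arr = np.asarray(samples)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return {
        "samples": arr,
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
        "ci95": (float(lo), float(hi)),
        "n_failed": failures,
    }


# ---------------------------------------------------------------------------
# information-criterion comparison
# ---------------------------------------------------------------------------

def model_compare(fits: dict[str, MixedModelFit], delta: float = 10.0) -> pd.DataFrame:
    """AIC/BIC comparison table; a model is favoured only beyond Δ>10."""
    ns = {f.n for f in fits.values()}
    resp = {f.response for f in fits.values()}
    if len(ns) != 1 or len(resp) != 1:
        raise ValueError("fits must share the same response and sample")
    tab = pd.DataFrame(
        {
            name: {
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic,
                "bic": f.bic,
            }
            for name, f in fits.items()
        }
    ).T
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab["delta_bic"] = tab["bic"] - tab["bic"].min()
    best = tab["bic"].idxmin()
    others = tab.loc[tab.index != best, "bic"]
    tab["favoured"] = False
    if len(others) and (others - tab.loc[best, "bic"]).min() > delta:
        tab.loc[best, "favoured"] = True
    return tab
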