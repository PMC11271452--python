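"""Profiled-REML fitter for the repeated-measures design used here.

The three chemistry models share one random-effects structure: a correlated
random intercept and age slope per fish, crossed with a random intercept
per calendar year,

    y = X beta + Z_fish b_f + Z_year u_y + eps,
    b_f ~ N(0, Sigma_f) (2x2),  u_y ~ N(0, sigma_y^2),  eps ~ N(0, sigma^2).

Fixed effects and sigma^2 are profiled out of the REML criterion, which is
minimised over the relative covariance factor (the per-fish lower-triangle
[[d1, 0], [od, d2]] and the year scale dy) with a deterministic start.  The
linear algebra follows the standard sparse-Cholesky mixed-model equations
(here dense, as q = 2*n_fish + n_years stays modest), so fits are exactly
reproducible.  Wald t tests use Satterthwaite degrees of freedom by
default ("residual" available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


@dataclass
class MixedModelResult:
    """Fit summary: fixed effects, variance components, R2, VIF, flags."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    df: np.ndarray
    sigma2: float
    fish_cov: np.ndarray  # 2x2 intercept/age-slope covariance
    year_var: float
    marginal_r2: float
    conditional_r2: float
    vif: dict
    n_obs: int
    n_fish: int
    n_years: int
    converged: bool
    singular: bool
    reml_criterion: float
    n_dropped: int = 0
    cov_beta: np.ndarray | None = None

    def fixed_effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "t": self.tvals,
                "df": self.df,
                "p": self.pvals,
            }
        )

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        q = stats.t.ppf(0.5 + level / 2, self.df)
        return pd.DataFrame(
            {
                "term": self.terms,
                "lo": self.beta - q * self.se,
                "hi": self.beta + q * self.se,
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "t": self.tvals.tolist(),
            "df": self.df.tolist(),
            "p": self.pvals.tolist(),
            "sigma2": self.sigma2,
            "fish_cov": self.fish_cov.tolist(),
            "year_var": self.year_var,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "vif": self.vif,
            "n_obs": self.n_obs,
            "n_fish": self.n_fish,
            "n_years": self.n_years,
            "converged": self.converged,
            "singular": self.singular,
        }


def _lambda_cols(M: np.ndarray, th: np.ndarray, F: int) -> np.ndarray:
    """Right-multiply by the relative covariance factor Lambda (blockwise)."""
    d1, od, d2, dy = th
    out = M.copy()
    c1 = M[..., 0 : 2 * F : 2]
    c2 = M[..., 1 : 2 * F : 2]
    out[..., 0 : 2 * F : 2] = d1 * c1 + od * c2
    out[..., 1 : 2 * F : 2] = d2 * c2
    out[..., 2 * F :] = dy * M[..., 2 * F :]
    return out


def _build_problem(y, X, age, fish_codes, year_codes):
    n = y.size
    F = int(fish_codes.max()) + 1
    Y = int(year_codes.max()) + 1
    q = 2 * F + Y
    Z = np.zeros((n, q))
    rows = np.arange(n)
    Z[rows, 2 * fish_codes] = 1.0
    Z[rows, 2 * fish_codes + 1] = age
    Z[rows, 2 * F + year_codes] = 1.0
    return {
        "ZtZ": Z.T @ Z,
        "ZtX": Z.T @ X,
        "Zty": Z.T @ y,
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
        "n": n,
        "p": X.shape[1],
        "F": F,
        "Y": Y,
    }


def _profiled_pieces(pr, th):
    """Cholesky pieces of the mixed-model equations at relative factor th."""
    F, q = pr["F"], 2 * pr["F"] + pr["Y"]
    LtZtZL = _lambda_cols(_lambda_cols(pr["ZtZ"], th, F).T, th, F).T
    A = LtZtZL + np.eye(q)
    L = linalg.cholesky(A, lower=True)
    LtZtX = _lambda_cols(pr["ZtX"].T, th, F).T
    LtZty = _lambda_cols(pr["Zty"], th, F)
    RZX = linalg.solve_triangular(L, LtZtX, lower=True)
    cu = linalg.solve_triangular(L, LtZty, lower=True)
    RXtRX = pr["XtX"] - RZX.T @ RZX
    RX = linalg.cholesky(RXtRX, lower=True)
    cbeta = linalg.solve_triangular(RX, pr["Xty"] - RZX.T @ cu, lower=True)
    beta = linalg.solve_triangular(RX.T, cbeta, lower=False)
    pwrss = pr["yty"] - float(cu @ cu) - float(cbeta @ cbeta)
    pwrss = max(pwrss, 1e-12)
    logdetL = float(np.sum(np.log(np.diag(L))))
    logdetRX = float(np.sum(np.log(np.diag(RX))))
    return L, RX, RXtRX, beta, pwrss, logdetL, logdetRX


def _reml_deviance(pr, th):
    _, _, _, _, pwrss, ldL, ldRX = _profiled_pieces(pr, th)
    nmp = pr["n"] - pr["p"]
    return 2 * ldL + 2 * ldRX + nmp * (1.0 + np.log(2 * np.pi * pwrss / nmp))


def _full_deviance(pr, th, log_s2):
    """Non-profiled REML deviance (sigma^2 free) for Satterthwaite."""
    s2 = np.exp(log_s2)
    _, _, _, _, pwrss, ldL, ldRX = _profiled_pieces(pr, th)
    nmp = pr["n"] - pr["p"]
    return 2 * ldL + 2 * ldRX + nmp * np.log(2 * np.pi * s2) + pwrss / s2


def _satterthwaite_df(pr, th, s2, RXtRX_inv, bounds_hit):
    """Per-coefficient Satterthwaite df from the REML information matrix."""
    p = pr["p"]
    nmp = pr["n"] - pr["p"]
    phi = np.append(th, np.log(s2))
    k = phi.size
    h = 1e-4 * np.maximum(np.abs(phi), 1.0)

    def dev(v):
        return _full_deviance(pr, v[:4], v[4])

    def cjj(v):
        _, _, RXtRX, _, _, _, _ = _profiled_pieces(pr, v[:4])
        return np.exp(v[4]) * np.diag(linalg.inv(RXtRX))

    # Hessian of the deviance (central differences)
    H = np.zeros((k, k))
    f0 = dev(phi)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (dev(phi + ei) - 2 * f0 + dev(phi - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                dev(phi + ei + ej) - dev(phi + ei - ej)
                - dev(phi - ei + ej) + dev(phi - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        vcov_phi = 2.0 * linalg.inv(H)
    except linalg.LinAlgError:
        return np.full(p, float(nmp))
    # gradient of each C_jj wrt phi
    G = np.zeros((k, p))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        G[i] = (cjj(phi + ei) - cjj(phi - ei)) / (2 * h[i])
    C0 = s2 * np.diag(RXtRX_inv)
    df = np.empty(p)
    for j in range(p):
        denom = float(G[:, j] @ vcov_phi @ G[:, j])
        df[j] = 2 * C0[j] ** 2 / denom if denom > 0 else nmp
    return np.clip(df, 1.0, float(nmp))


def fit_crossed_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: list[str],
    fish_col: str = "fish_id",
    year_col: str = "calendar_year",
    age_col: str = "age",
    log_response: bool = True,
    df_method: str = "satterthwaite",
    vif_fn=None,
) -> MixedModelResult:
    """Fit response ~ fixed + (age | fish) + (1 | year) by REML.

    Rows with missing or (if log-transforming) non-positive response are
    dropped with a count; the fit is deterministic.
    """
    cols = list(dict.fromkeys([response, age_col, fish_col, year_col, *fixed]))
    df = table[cols].copy()
    n0 = len(df)
    df = df.dropna()
    if log_response:
        df = df[df[response] > 0]
    n_dropped = n0 - len(df)
    y = np.log(df[response].to_numpy()) if log_response else df[response].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(float) for c in fixed]
    )
    terms = ["(Intercept)"] + list(fixed)
    fish_codes = pd.Categorical(df[fish_col]).codes.astype(int)
    year_codes = pd.Categorical(df[year_col]).codes.astype(int)
    age = df[age_col].to_numpy(float)
    pr = _build_problem(y, X, age, fish_codes, year_codes)

    x0 = np.array([1.0, 0.0, 1.0, 1.0])
    bounds = [(0.0, None), (None, None), (0.0, None), (0.0, None)]
    res = optimize.minimize(
        lambda th: _reml_deviance(pr, th), x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        res2 = optimize.minimize(
            lambda th: _reml_deviance(pr, th), res.x, method="Powell",
            bounds=bounds, options={"maxiter": 2000, "xtol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    th = res.x
    converged = bool(res.success)
    singular = bool(min(th[0], th[2], th[3]) < 1e-4)

    L, RX, RXtRX, beta, pwrss, _, _ = _profiled_pieces(pr, th)
    nmp = pr["n"] - pr["p"]
    sigma2 = pwrss / nmp
    RXtRX_inv = linalg.inv(RXtRX)
    cov_beta = sigma2 * RXtRX_inv
    se = np.sqrt(np.diag(cov_beta))
    if df_method == "satterthwaite":
        dfree = _satterthwaite_df(pr, th, sigma2, RXtRX_inv, singular)
    else:
        dfree = np.full(pr["p"], float(nmp))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfree)

    lam = np.array([[th[0], 0.0], [th[1], th[2]]])
    fish_cov = sigma2 * lam @ lam.T
    year_var = sigma2 * th[3] ** 2

    # Nakagawa-style variance partition
    fitted_fixed = X @ beta
    var_f = float(np.var(fitted_fixed))
    var_r = (
        fish_cov[0, 0]
        + 2 * fish_cov[0, 1] * age.mean()
        + fish_cov[1, 1] * float(np.mean(age**2))
        + year_var
    )
    tot = var_f + var_r + sigma2
    marginal_r2 = var_f / tot
    conditional_r2 = (var_f + var_r) / tot

    vif = {}
    if len(fixed) >= 2:
        vif = vif_screen(df[list(fixed)])
    return MixedModelResult(
        terms=terms,
        beta=beta,
        se=se,
        tvals=tvals,
        pvals=pvals,
        df=dfree,
        sigma2=float(sigma2),
        fish_cov=fish_cov,
        year_var=float(year_var),
        marginal_r2=float(marginal_r2),
        conditional_r2=float(conditional_r2),
        vif=vif,
        n_obs=pr["n"],
        n_fish=pr["F"],
        n_years=pr["Y"],
        converged=converged,
        singular=singular,
        reml_criterion=float(res.fun),
        n_dropped=n_dropped,
        cov_beta=cov_beta,
    )


def vif_screen(design: pd.DataFrame, flag_threshold: float = 5.0) -> dict:
    """Variance inflation factors of a fixed-effects covariate table.

    VIF_j = 1/(1 - R2_j) from regressing covariate j on the others (with
    intercept).  A perfectly collinear column reports ``inf``.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if (design.nunique() <= 1).any():
        raise ValueError("constant covariate column in VIF design")
    Xc = sm.add_constant(design.to_numpy(float), has_constant="add")
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(design.columns):
            v = variance_inflation_factor(Xc, j + 1)
            out[str(name)] = float(v) if np.isfinite(v) else float("inf")
    return out
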