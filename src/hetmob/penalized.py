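"""Penalized estimation machinery.

Three estimators used throughout the analysis:

* a maximum-penalized-likelihood ("pseudo-Bayesian") multilevel linear model:
  the Gaussian mixed-model likelihood plus a Wishart log-prior on the
  random-effects covariance, maximized jointly.  The prior (default nu=4,
  scale 0.05*I) acts as a weakly informative regularizer that rules out
  boundary (zero-variance) fits, which matters with only two trials;
* OLS with small-sample bias-reduced cluster-robust variance (CR2) and
  Satterthwaite degrees of freedom, the sensitivity analysis engine;
* an L1-penalized multivariable interaction model (prognostic main effects
  plus prescriptive treatment-by-moderator terms) with BIC-selected penalty.

The random-effects design is {trial intercept, trial-by-treatment slope}
(q=2) by default, matching a one-stage individual-participant-data
meta-analysis of two pooled trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import CollinearityError, ConfigurationError, ConvergenceError
from .synthetic import moderator_numeric

__all__ = [
    "WishartPrior",
    "MPLFit",
    "OLSCR2Fit",
    "LassoFit",
    "wishart_log_penalty",
    "design_matrix",
    "fit_mpl_lmm",
    "fit_ols_cr2",
    "fit_lasso_interactions",
]


@dataclass(frozen=True)
class WishartPrior:
    """Wishart prior on the random-effects covariance matrix.

    nu degrees of freedom and a q x q positive-definite scale matrix;
    defaults nu=4, scale=0.05*I.  Requires nu > q - 1.
    """

    nu: float = 4.0
    scale: np.ndarray | float = 0.05

    def scale_matrix(self, q: int) -> np.ndarray:
        s = np.asarray(self.scale, dtype=float)
        if s.ndim == 0:
            s = float(s) * np.eye(q)
        if s.shape != (q, q):
            raise ConfigurationError(f"prior scale must be scalar or {q}x{q}")
        if not np.allclose(s, s.T):
            raise ConfigurationError("prior scale must be symmetric")
        if np.linalg.eigvalsh(s).min() <= 0:
            raise ConfigurationError("prior scale must be positive-definite")
        if self.nu <= q - 1:
            raise ConfigurationError("Wishart prior requires nu > q - 1")
        return s


def wishart_log_penalty(cov: np.ndarray, prior: WishartPrior) -> float:
    """Unnormalized Wishart(nu, scale) log-density at ``cov``:
    ((nu - q - 1)/2) log|cov| - tr(scale^{-1} cov)/2."""
    cov = np.asarray(cov, dtype=float)
    q = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ConfigurationError("cov must be positive-definite")
    s = prior.scale_matrix(q)
    return 0.5 * (prior.nu - q - 1) * logdet - 0.5 * float(
        np.trace(np.linalg.solve(s, cov))
    )


# ---------------------------------------------------------------------------
# design matrices


def _term_column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name == "treatment":
        return (table["arm"].astype(str) == "intervention").to_numpy(dtype=float)
    return moderator_numeric(table, name) if name in table.columns else _fail(name)


def _fail(name: str):
    raise ConfigurationError(f"unknown design term component {name!r}")


def design_matrix(
    table: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix from a small term grammar.

    Terms: ``"1"`` (intercept), ``"trial"`` (one indicator per trial level,
    i.e. stratified intercepts), ``"trial:x"`` (per-trial copies of numeric
    column x), ``"treatment"`` (0/1 intervention indicator), ``"a:b"``
    (elementwise product) and plain column names (binary moderators become
    0/1 indicators of their positive level).  Raises
    :class:`CollinearityError` naming aliased columns when the result is
    rank-deficient.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        if term == "1":
            cols.append(np.ones(len(table)))
            names.append("(Intercept)")
        elif term == "trial":
            for level in sorted(table["trial"].astype(str).unique()):
                cols.append((table["trial"].astype(str) == level).to_numpy(dtype=float))
                names.append(f"trial[{level}]")
        elif term.startswith("trial:"):
            base = term.split(":", 1)[1]
            x = _term_column(table, base)
            for level in sorted(table["trial"].astype(str).unique()):
                mask = (table["trial"].astype(str) == level).to_numpy(dtype=float)
                cols.append(mask * x)
                names.append(f"trial[{level}]:{base}")
        elif ":" in term:
            a, b = term.split(":", 1)
            cols.append(_term_column(table, a) * _term_column(table, b))
            names.append(term)
        else:
            cols.append(_term_column(table, term))
            names.append(term)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns that are linear combinations of their predecessors
        aliased = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append(names[j])
        raise CollinearityError(f"aliased design columns: {aliased}")
    return X, names


# ---------------------------------------------------------------------------
# MPL linear mixed model


@dataclass
class MPLFit:
    """A fitted maximum-penalized-likelihood multilevel linear model."""

    coef_names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    ranef_cov: np.ndarray
    ranef_names: list[str]
    sigma2: float
    penalized_loglik: float
    scores: np.ndarray
    converged: bool
    n_obs: int

    @property
    def fixed_coefs(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.beta))

    @property
    def fixed_se(self) -> dict[str, float]:
        return dict(zip(self.coef_names, np.sqrt(np.diag(self.cov_beta))))

    @property
    def tvalues(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.cov_beta))
        return dict(zip(self.coef_names, self.beta / se))

    @property
    def pvalues(self) -> dict[str, float]:
        # normal reference: trial-level df are ill-defined with two clusters
        se = np.sqrt(np.diag(self.cov_beta))
        z = np.abs(self.beta / se)
        return dict(zip(self.coef_names, 2.0 * stats.norm.sf(z)))

    @property
    def tau2_intercept(self) -> float:
        return float(self.ranef_cov[0, 0])

    @property
    def tau2_slope(self) -> float:
        if self.ranef_cov.shape[0] < 2:
            return 0.0
        return float(self.ranef_cov[1, 1])

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        j = self.coef_names.index(name)
        se = float(np.sqrt(self.cov_beta[j, j]))
        return float(self.beta[j] - z * se), float(self.beta[j] + z * se)


def _random_design(table: pd.DataFrame, random_terms: Sequence[str]) -> np.ndarray:
    cols = []
    for term in random_terms:
        if term in ("1", "intercept"):
            cols.append(np.ones(len(table)))
        else:
            cols.append(_term_column(table, term))
    return np.column_stack(cols)


def _ols_fit(X, names, y, n) -> MPLFit:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    p = X.shape[1]
    sigma2_ml = rss / n
    sigma2_ub = rss / max(n - p, 1)
    XtX_inv = np.linalg.inv(X.T @ X)
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + n)
    scores = X * (resid / sigma2_ml)[:, None]
    return MPLFit(
        coef_names=names,
        beta=beta,
        cov_beta=sigma2_ub * XtX_inv,
        ranef_cov=np.zeros((0, 0)),
        ranef_names=[],
        sigma2=sigma2_ml,
        penalized_loglik=loglik,
        scores=scores,
        converged=True,
        n_obs=n,
    )


def fit_mpl_lmm(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: Sequence[str],
    random_terms: Sequence[str] = ("intercept", "treatment"),
    prior: WishartPrior | None = WishartPrior(),
    group: str = "trial",
    max_iter: int = 4000,
) -> MPLFit:
    """Fit y = X beta + Z u + e with u ~ N(0, G) per group, e ~ N(0, s2 I),
    maximizing log-likelihood + Wishart log-prior on G.

    With fewer than two groups, no random terms, or ``prior=None`` together
    with a single group, the fit degenerates to plain OLS (returned with an
    empty random-effects covariance).  The fixed-coefficient covariance is
    the GLS information matrix (X' V^-1 X)^{-1} at the optimum; per-
    observation score rows are x_i * (V^-1 r)_i, whose columns sum to zero
    at the optimum.
    """
    if table[outcome].isna().any():
        raise ConfigurationError(f"missing values in outcome column {outcome!r}")
    y = table[outcome].to_numpy(dtype=float)
    X, names = design_matrix(table, fixed_terms)
    groups = table[group].astype(str).to_numpy()
    if len(set(groups)) < 2 or not random_terms:
        return _ols_fit(X, names, y, len(y))
    if prior is None:
        raise ConfigurationError(
            "a Wishart prior is required with multiple groups; pass random_terms=()"
            " for a fixed-effects fit"
        )
    Z = _random_design(table, random_terms)
    ranef_names = ["intercept" if t in ("1", "intercept") else t for t in random_terms]
    return mpl_lmm_arrays(y, X, names, Z, groups, prior,
                          ranef_names=ranef_names, max_iter=max_iter)


def mpl_lmm_arrays(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    Z: np.ndarray,
    groups: np.ndarray,
    prior: WishartPrior,
    ranef_names: Sequence[str] | None = None,
    max_iter: int = 4000,
) -> MPLFit:
    """Array-level MPL mixed-model core (see :func:`fit_mpl_lmm`)."""
    names = list(names)
    n, k = X.shape
    levels = sorted(set(groups))
    q = Z.shape[1]
    S = prior.scale_matrix(q)
    S_inv = np.linalg.inv(S)

    # per-group cross-products, stacked so each objective evaluation is a
    # handful of batched O(G q^2 (q+k)) operations
    idx = {lv: np.flatnonzero(groups == lv) for lv in levels}
    G_n = len(levels)
    ZtZ_all = np.empty((G_n, q, q))
    ZtX_all = np.empty((G_n, q, k))
    Zty_all = np.empty((G_n, q))
    ng_all = np.empty(G_n)
    XtX_sum = X.T @ X
    Xty_sum = X.T @ y
    yty_sum = float(y @ y)
    for gi, lv in enumerate(levels):
        i = idx[lv]
        Xg, Zg, yg = X[i], Z[i], y[i]
        ZtZ_all[gi] = Zg.T @ Zg
        ZtX_all[gi] = Zg.T @ Xg
        Zty_all[gi] = Zg.T @ yg
        ng_all[gi] = len(i)

    def unpack(theta):
        log_s = theta[0]
        s2 = np.exp(2.0 * log_s)
        L = np.zeros((q, q))
        pos = 1
        for j in range(q):
            for m in range(j + 1):
                if m == j:
                    L[j, j] = np.exp(theta[pos])
                else:
                    L[j, m] = theta[pos]
                pos += 1
        G = L @ L.T
        return s2, G

    n_theta = 1 + q * (q + 1) // 2

    def components(s2, G):
        G_inv = np.linalg.inv(G)
        logdet_G = np.linalg.slogdet(G)[1]
        M_all = s2 * G_inv[None, :, :] + ZtZ_all
        M_chol = np.linalg.cholesky(M_all)
        logdet_M = 2.0 * np.log(
            M_chol[:, np.arange(q), np.arange(q)]
        ).sum()
        W_ZX = np.linalg.solve(M_all, ZtX_all)            # (G, q, k)
        W_Zy = np.linalg.solve(M_all, Zty_all[..., None])[..., 0]  # (G, q)
        A = (XtX_sum - np.einsum("gqk,gql->kl", ZtX_all, W_ZX)) / s2
        b = (Xty_sum - np.einsum("gqk,gq->k", ZtX_all, W_Zy)) / s2
        yy = (yty_sum - float((Zty_all * W_Zy).sum())) / s2
        logdet_V = float(((ng_all - q) * np.log(s2)).sum()
                         + G_n * logdet_G + logdet_M)
        return A, b, yy, logdet_V

    def neg_penalized(theta):
        try:
            s2, G = unpack(theta)
            A, b, yy, logdet_V = components(s2, G)
            beta = np.linalg.solve(A, b)
            quad = yy - b @ beta
            loglik = -0.5 * (logdet_V + quad + n * np.log(2 * np.pi))
            pen = 0.5 * (prior.nu - q - 1) * np.linalg.slogdet(G)[1] - 0.5 * float(
                np.trace(S_inv @ G)
            )
            return -(loglik + pen)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    # start from OLS residual scale and a small, PD random-effects covariance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    s0 = max(float(np.std(resid0)), 1e-3)
    x0 = np.zeros(n_theta)
    x0[0] = np.log(s0)
    pos = 1
    for j in range(q):
        for m in range(j + 1):
            x0[pos] = np.log(0.3) if m == j else 0.0
            pos += 1

    # convergence: 1e-8 relative change of the penalized objective
    f0 = neg_penalized(x0)
    res = optimize.minimize(
        neg_penalized,
        x0,
        method="Nelder-Mead",
        options=dict(maxiter=max_iter, xatol=1e-5,
                     fatol=1e-8 * max(1.0, abs(f0)), maxfev=max_iter),
    )
    if not res.success:
        res2 = optimize.minimize(
            neg_penalized, res.x, method="Powell", options=dict(maxiter=max_iter)
        )
        if res2.fun < res.fun:
            res = res2
    converged = bool(np.isfinite(res.fun) and res.fun < 1e11)
    if not converged:
        raise ConvergenceError("MPL mixed-model fit did not converge")

    s2, G = unpack(res.x)
    A, b, yy, logdet_V = components(s2, G)
    beta = np.linalg.solve(A, b)
    cov_beta = np.linalg.inv(A)
    # per-observation scores: x_i * (V^{-1} r)_i
    r = y - X @ beta
    Vinv_r = np.empty(n)
    G_inv = np.linalg.inv(G)
    for gi, lv in enumerate(levels):
        i = idx[lv]
        Zg = Z[i]
        M = s2 * G_inv + ZtZ_all[gi]
        Vinv_r[i] = (r[i] - Zg @ np.linalg.solve(M, Zg.T @ r[i])) / s2
    scores = X * Vinv_r[:, None]
    quad = yy - b @ beta
    loglik = -0.5 * (logdet_V + quad + n * np.log(2 * np.pi))
    pen = wishart_log_penalty(G, prior)
    if ranef_names is None:
        ranef_names = [f"z{j}" for j in range(q)]
    return MPLFit(
        coef_names=names,
        beta=beta,
        cov_beta=cov_beta,
        ranef_cov=G,
        ranef_names=list(ranef_names),
        sigma2=s2,
        penalized_loglik=float(loglik + pen),
        scores=scores,
        converged=True,
        n_obs=n,
    )


def predict_random_effects(fit: MPLFit, table: pd.DataFrame,
                           random_terms: Sequence[str] = ("intercept", "treatment"),
                           outcome: str = "phq9_post",
                           fixed_terms: Sequence[str] | None = None,
                           group: str = "trial") -> np.ndarray:
    """Empirical-Bayes (BLUP) contribution Z u-hat per row, given a fit whose
    design matched ``fixed_terms`` on the same table."""
    if fixed_terms is None:
        raise ConfigurationError("fixed_terms required to reconstruct the design")
    y = table[outcome].to_numpy(dtype=float)
    X, _ = design_matrix(table, fixed_terms)
    Z = _random_design(table, random_terms)
    r = y - X @ fit.beta
    groups = table[group].astype(str).to_numpy()
    out = np.zeros(len(table))
    if fit.ranef_cov.size == 0:
        return out
    G_inv = np.linalg.inv(fit.ranef_cov)
    for lv in sorted(set(groups)):
        i = np.flatnonzero(groups == lv)
        Zg = Z[i]
        M = fit.sigma2 * G_inv + Zg.T @ Zg
        u = np.linalg.solve(M, Zg.T @ r[i])
        out[i] = Zg @ u
    return out


# ---------------------------------------------------------------------------
# OLS with CR2 cluster-robust variance


@dataclass
class OLSCR2Fit:
    """OLS point estimates with bias-reduced linearization (CR2) variance and
    Satterthwaite degrees of freedom per coefficient."""

    coef_names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    satterthwaite_df: np.ndarray
    n_clusters: int
    n_obs: int

    @property
    def fixed_coefs(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.beta))

    @property
    def fixed_se(self) -> dict[str, float]:
        return dict(zip(self.coef_names, np.sqrt(np.diag(self.vcov))))

    @property
    def tvalues(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.beta / np.sqrt(np.diag(self.vcov))))

    @property
    def pvalues(self) -> dict[str, float]:
        t = self.beta / np.sqrt(np.diag(self.vcov))
        return {
            name: 2.0 * stats.t.sf(abs(ti), dfi)
            for name, ti, dfi in zip(self.coef_names, t, self.satterthwaite_df)
        }


def fit_ols_cr2(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: Sequence[str],
    cluster: str = "trial",
) -> OLSCR2Fit:
    """OLS with CR2 cluster-robust variance.

    The per-cluster leverage adjustment is the symmetric inverse square root
    of (I - H_gg); Satterthwaite degrees of freedom are computed per
    coefficient from the homoskedastic working model (Bell-McCaffrey).
    """
    y = table[outcome].to_numpy(dtype=float)
    X, names = design_matrix(table, fixed_terms)
    n, k = X.shape
    groups = table[cluster].astype(str).to_numpy()
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ConfigurationError("CR2 requires at least two clusters")
    B = X.T @ X
    B_inv = np.linalg.inv(B)
    beta = B_inv @ (X.T @ y)
    e = y - X @ beta

    meat = np.zeros((k, k))
    adj: dict[str, np.ndarray] = {}
    for lv in levels:
        i = np.flatnonzero(groups == lv)
        Xg = X[i]
        Hgg = Xg @ B_inv @ Xg.T
        IH = np.eye(len(i)) - Hgg
        w, V = np.linalg.eigh(IH)
        pos = w > 1e-10
        if not pos.any():
            raise ConfigurationError(
                f"cluster {lv!r} has too few observations relative to the fixed "
                "terms for the CR2 adjustment; drop terms or merge clusters"
            )
        # Moore-Penrose symmetric inverse square root: with cluster-absorbing
        # fixed terms (e.g. trial dummies) I - H_gg is singular by design
        inv_sqrt = np.where(pos, 1.0 / np.sqrt(np.where(pos, w, 1.0)), 0.0)
        Ag = (V * inv_sqrt) @ V.T
        adj[lv] = Ag
        u = Xg.T @ Ag @ e[i]
        meat += np.outer(u, u)
    vcov = B_inv @ meat @ B_inv

    # Satterthwaite df per coefficient under the homoskedastic working model
    dfs = np.empty(k)
    for j in range(k):
        ell = np.zeros(k)
        ell[j] = 1.0
        zs, ts = [], []
        for lv in levels:
            i = np.flatnonzero(groups == lv)
            Xg = X[i]
            z = adj[lv] @ Xg @ B_inv @ ell
            zs.append(z)
            ts.append(Xg.T @ z)
        G = len(levels)
        C = np.empty((G, G))
        for a in range(G):
            for b_ in range(G):
                C[a, b_] = -ts[a] @ B_inv @ ts[b_]
            C[a, a] += zs[a] @ zs[a]
        tr = np.trace(C)
        tr2 = float((C * C).sum())
        dfs[j] = tr**2 / tr2 if tr2 > 0 else np.inf
    return OLSCR2Fit(
        coef_names=names,
        beta=beta,
        vcov=vcov,
        satterthwaite_df=dfs,
        n_clusters=len(levels),
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# LASSO interaction model


@dataclass
class LassoFit:
    """L1-penalized interaction model along a penalty path with BIC selection."""

    lambdas: np.ndarray
    coef_names: list[str]
    penalized_mask: np.ndarray
    coef_path: dict[float, np.ndarray]
    bic_path: dict[float, float]
    lambda_: float
    selected_coefs: dict[str, float] = field(default_factory=dict)

    def n_nonzero(self, lam: float) -> int:
        coefs = self.coef_path[lam]
        return int((np.abs(coefs[self.penalized_mask]) > 0).sum())


def _coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    penalized: np.ndarray,
    lam: float,
    beta0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> np.ndarray:
    n, p = X.shape
    gram = X.T @ X / n
    xty = X.T @ y / n
    beta = beta0.copy()
    diag = np.diag(gram).copy()
    diag[diag == 0] = 1.0
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            rho = xty[j] - gram[j] @ beta + diag[j] * beta[j]
            if penalized[j]:
                new = np.sign(rho) * max(abs(rho) - lam, 0.0) / diag[j]
            else:
                new = rho / diag[j]
            d = abs(new - beta[j])
            if d > delta:
                delta = d
            beta[j] = new
        if delta < tol:
            break
    return beta


def fit_lasso_interactions(
    table: pd.DataFrame,
    moderators: Sequence[str],
    lambda_grid: Sequence[float],
    outcome: str = "phq9_post",
    baseline: str = "phq9_baseline",
) -> LassoFit:
    """LASSO over {trial intercepts, baseline, treatment (unpenalized)} +
    {standardized moderators, treatment x moderators (penalized)}.

    Moderators are standardized internally (mean 0, SD 1).  The trial enters
    as stratified fixed intercepts: with two clusters a random-intercept fit
    and stratified intercepts coincide up to shrinkage, and the L1 path
    stays a plain convex problem.  BIC = n log(RSS/n) + df log(n) with df =
    number of nonzero coefficients; the selected coefficients are those at
    the BIC minimum.
    """
    lambda_grid = np.asarray(list(lambda_grid), dtype=float)
    if lambda_grid.size == 0:
        raise ConfigurationError("lambda_grid must be non-empty")
    if (lambda_grid < 0).any():
        raise ConfigurationError("lambda_grid must be non-negative")
    if not np.all(np.diff(lambda_grid) >= 0):
        logging.getLogger(__name__).info("lambda_grid not sorted; sorting")
    lambdas = np.sort(lambda_grid)

    y = table[outcome].to_numpy(dtype=float)
    n = len(y)
    cols: list[np.ndarray] = []
    names: list[str] = []
    pen: list[bool] = []
    for level in sorted(table["trial"].astype(str).unique()):
        cols.append((table["trial"].astype(str) == level).to_numpy(dtype=float))
        names.append(f"trial[{level}]")
        pen.append(False)
    base = table[baseline].to_numpy(dtype=float)
    cols.append(base)
    names.append(baseline)
    pen.append(False)
    treat = (table["arm"].astype(str) == "intervention").to_numpy(dtype=float)
    cols.append(treat)
    names.append("treatment")
    pen.append(False)
    for name in moderators:
        x = moderator_numeric(table, name)
        sd = x.std()
        if sd == 0:
            raise ConfigurationError(f"moderator {name!r} is constant")
        z = (x - x.mean()) / sd
        cols.append(z)
        names.append(f"{name}[std]")
        pen.append(True)
        cols.append(treat * z)
        names.append(f"treatment:{name}[std]")
        pen.append(True)
    X = np.column_stack(cols)
    penalized = np.array(pen)

    coef_path: dict[float, np.ndarray] = {}
    bic_path: dict[float, float] = {}
    beta = np.zeros(X.shape[1])
    for lam in lambdas[::-1]:  # descending: warm starts from the sparse end
        beta = _coordinate_descent(X, y, penalized, float(lam), beta)
        coef_path[float(lam)] = beta.copy()
        resid = y - X @ beta
        rss = float(resid @ resid)
        df = int((~penalized).sum()) + int((np.abs(beta[penalized]) > 0).sum())
        bic_path[float(lam)] = n * np.log(max(rss, 1e-300) / n) + df * np.log(n)
    lam_sel = min(bic_path, key=lambda lam: (bic_path[lam], lam))
    fit = LassoFit(
        lambdas=lambdas,
        coef_names=names,
        penalized_mask=penalized,
        coef_path=coef_path,
        bic_path=bic_path,
        lambda_=lam_sel,
        selected_coefs=dict(zip(names, coef_path[lam_sel])),
    )
    return fit
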