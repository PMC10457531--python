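"""Multilevel multiple imputation by chained equations.

Missing values are imputed separately within each treatment arm (groupwise
imputation), iterating conditional models column by column.  Numeric
columns are drawn from the posterior predictive of a two-level normal model
(trial random intercept, estimated by maximum penalized likelihood with a
Wishart prior, so heterogeneity never collapses onto the boundary);
categorical columns are imputed by predictive mean matching against the
pmm_donors nearest observed donors on the linear predictor.  Predictors
enter a column's model only when their pairwise-complete absolute
correlation with it reaches the pruning threshold; trial and arm are always
retained as structural variables.

Pooling follows Rubin's rules with Barnard-Rubin small-sample degrees of
freedom.  Nonparametric downstream stages (forests, trees) operate on a
single aggregated dataset: across-imputation means on the instrument grid
for numeric cells, across-imputation modes for categorical cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .penalized import WishartPrior, design_matrix, fit_mpl_lmm
from .synthetic import INSTRUMENT_RANGES, POSITIVE_LEVEL

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationConfig",
    "ImputedStack",
    "PooledEstimate",
    "build_predictor_matrix",
    "impute",
    "rubin_pool",
    "aggregate_stack",
]


@dataclass
class ImputationConfig:
    """Settings of the chained-equations run.

    m=50 completed datasets by default; predictors pruned below |r|=0.05;
    imputation runs separately per arm; the two-level normal model uses the
    same weakly informative Wishart prior as the analysis models.
    """

    m: int = 50
    n_iterations: int = 10
    prune_threshold: float = 0.05
    pmm_donors: int = 5
    groupwise_by: str = "arm"
    prior: WishartPrior = field(default_factory=WishartPrior)
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if not (0.0 <= self.prune_threshold < 1.0):
            raise ConfigurationError("prune_threshold must lie in [0, 1)")
        if self.pmm_donors < 1:
            raise ConfigurationError("pmm_donors must be >= 1")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


@dataclass
class ImputedStack:
    """m completed copies of a participant table plus the audit trail."""

    tables: list[pd.DataFrame]
    predictor_matrix: pd.DataFrame
    methods: dict[str, str]
    trace: pd.DataFrame
    missing_mask: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.tables)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m point estimates and variances."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    m: int


def _is_numeric_column(table: pd.DataFrame, col: str) -> bool:
    return pd.api.types.is_numeric_dtype(table[col])


def _numeric_view(table: pd.DataFrame, col: str) -> np.ndarray:
    """Numeric working representation of a column, NaN where missing."""
    if _is_numeric_column(table, col):
        return table[col].to_numpy(dtype=float)
    vals = table[col]
    if col in POSITIVE_LEVEL:
        out = np.where(vals.isna(), np.nan,
                       (vals.astype(object) == POSITIVE_LEVEL[col]).astype(float))
        return np.asarray(out, dtype=float)
    codes = pd.Categorical(vals).codes.astype(float)
    codes[codes < 0] = np.nan
    return codes


def build_predictor_matrix(table: pd.DataFrame, config: ImputationConfig) -> pd.DataFrame:
    """Binary variable x variable inclusion matrix for the chained equations.

    Row = column to impute, column = candidate predictor; a predictor is
    kept when its pairwise-complete absolute correlation with the target is
    at least ``prune_threshold``.  Constant predictors (correlation
    undefined) are excluded with a logged warning; trial and arm are always
    retained as structural variables.
    """
    config.validate()
    candidates = [c for c in table.columns
                  if c not in ("participant_id", "trial", "arm")]
    targets = [c for c in candidates if table[c].isna().any()]
    for col in targets:
        if table[col].notna().sum() == 0:
            raise ConfigurationError(f"column {col!r} has no observed values")
    mat = pd.DataFrame(0, index=targets, columns=candidates + ["trial", "arm"], dtype=int)
    for target in targets:
        ty = _numeric_view(table, target)
        for other in candidates:
            if other == target:
                continue
            tx = _numeric_view(table, other)
            both = ~np.isnan(ty) & ~np.isnan(tx)
            if both.sum() < 3:
                continue
            if tx[both].std() == 0 or ty[both].std() == 0:
                logger.warning(
                    "predictor %r constant on the observed overlap with %r; excluded",
                    other, target,
                )
                continue
            r = np.corrcoef(tx[both], ty[both])[0, 1]
            if abs(r) >= config.prune_threshold:
                mat.loc[target, other] = 1
        mat.loc[target, "trial"] = 1
        mat.loc[target, "arm"] = 1
    return mat


def _two_level_normal_draw(
    sub: pd.DataFrame,
    target: str,
    predictors: list[str],
    prior: WishartPrior,
    rng: np.random.Generator,
    obs: np.ndarray,
) -> np.ndarray:
    """Posterior-predictive draw for the missing entries of ``target`` from a
    two-level normal model with a trial random intercept.

    Approximate Bayesian step: beta ~ N(beta_hat, cov_hat), sigma^2 from its
    scaled inverse chi-square, trial intercepts at their empirical-Bayes
    values given the drawn residual scale.
    """
    work = pd.DataFrame({"trial": sub["trial"].astype(str).to_numpy()})
    for p in predictors:
        work[p] = _numeric_view(sub, p)
    work["__y__"] = _numeric_view(sub, target)
    terms = ["1"] + predictors
    obs_df = work.loc[obs].reset_index(drop=True)
    mis_df = work.loc[~obs].reset_index(drop=True)
    if obs_df["trial"].nunique() >= 2:
        fit = fit_mpl_lmm(obs_df, "__y__", terms, random_terms=("intercept",), prior=prior)
    else:
        fit = fit_mpl_lmm(obs_df, "__y__", terms, random_terms=())
    beta_draw = rng.multivariate_normal(fit.beta, fit.cov_beta, method="svd")
    df_res = max(len(obs_df) - len(fit.beta), 2)
    sigma2_draw = fit.sigma2 * df_res / rng.chisquare(df_res)
    # empirical-Bayes trial intercepts from residuals at the point estimate
    Xo, _ = design_matrix(obs_df, terms)
    resid = obs_df["__y__"].to_numpy() - Xo @ fit.beta
    u: dict[str, float] = {}
    if fit.ranef_cov.size:
        tau2 = float(fit.ranef_cov[0, 0])
        for lv in obs_df["trial"].unique():
            r = resid[(obs_df["trial"] == lv).to_numpy()]
            u[lv] = tau2 * r.sum() / (len(r) * tau2 + fit.sigma2)
    Xm, _ = design_matrix(mis_df, terms)
    mu = Xm @ beta_draw + np.array([u.get(lv, 0.0) for lv in mis_df["trial"]])
    return mu + rng.normal(0.0, np.sqrt(sigma2_draw), size=len(mis_df))


def _pmm_draw(
    sub: pd.DataFrame,
    target: str,
    predictors: list[str],
    donors: int,
    rng: np.random.Generator,
    obs: np.ndarray,
) -> np.ndarray:
    """Predictive mean matching: for each missing case draw uniformly among
    the ``donors`` observed rows closest on the linear predictor; imputed
    values therefore always belong to the observed support."""
    y = _numeric_view(sub, target)
    cols = [np.ones(len(sub))]
    for p in predictors:
        cols.append(np.nan_to_num(_numeric_view(sub, p)))
    X = np.column_stack(cols)
    Xo, yo = X[obs], y[obs]
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    sigma2 = float(resid @ resid) / max(len(yo) - X.shape[1], 1)
    cov = sigma2 * np.linalg.pinv(Xo.T @ Xo)
    beta_draw = rng.multivariate_normal(beta, cov, method="svd")
    pred_obs = Xo @ beta
    pred_mis = X[~obs] @ beta_draw
    observed_values = sub.loc[obs, target].to_numpy()
    out = np.empty(len(pred_mis), dtype=object)
    for i, pm in enumerate(pred_mis):
        order = np.argsort(np.abs(pred_obs - pm), kind="stable")[:donors]
        out[i] = observed_values[order[rng.integers(len(order))]]
    return out


def impute(table: pd.DataFrame, config: ImputationConfig) -> ImputedStack:
    """Run groupwise chained equations and return m completed tables.

    Columns are visited in increasing order of missingness fraction within
    each sweep; sweeps run separately within each level of
    ``groupwise_by``.  Observed cells are never altered; a table with no
    missing cells returns m identical copies.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    if table[config.groupwise_by].isna().any():
        raise ConfigurationError(f"{config.groupwise_by!r} must be fully observed")
    table = table.reset_index(drop=True)
    predictor_matrix = build_predictor_matrix(table, config)
    targets = list(predictor_matrix.index)
    methods = {
        col: ("two-level-normal" if _is_numeric_column(table, col) else "pmm")
        for col in targets
    }
    for col in table.columns:
        methods.setdefault(col, "none")
    missing_mask = table[targets].isna() if targets else pd.DataFrame(index=table.index)
    if not targets:
        trace = pd.DataFrame(columns=["imputation", "iteration", "column", "mean", "sd"])
        return ImputedStack([table.copy() for _ in range(config.m)],
                            predictor_matrix, methods, trace, missing_mask)

    order = sorted(targets, key=lambda c: table[c].isna().mean())
    rng_master = np.random.default_rng([int(config.seed), 77])
    groups = table[config.groupwise_by].astype(str)
    tables: list[pd.DataFrame] = []
    trace_rows = []
    for mi in range(config.m):
        rng = np.random.default_rng(rng_master.integers(2**31))
        work = table.copy()
        for col in order:
            miss = missing_mask[col]
            obs_vals = work.loc[~miss, col].to_numpy()
            work.loc[miss, col] = rng.choice(obs_vals, size=int(miss.sum()))
        for it in range(config.n_iterations):
            for col in order:
                miss_orig = missing_mask[col]
                predictors = [
                    c for c in predictor_matrix.columns
                    if predictor_matrix.loc[col, c] == 1 and c not in ("trial", "arm")
                ]
                for gname in groups.unique():
                    gsel = (groups == gname).to_numpy()
                    sel_miss = miss_orig.to_numpy() & gsel
                    if not sel_miss.any():
                        continue
                    sub = work.loc[gsel].reset_index(drop=True)
                    sub_obs = ~miss_orig.to_numpy()[gsel]
                    usable = [p for p in predictors
                              if np.nanstd(_numeric_view(sub, p)) > 0]
                    if methods[col] == "two-level-normal":
                        draws = _two_level_normal_draw(
                            sub, col, usable, config.prior, rng, sub_obs
                        )
                        lo, hi = INSTRUMENT_RANGES.get(col, (-np.inf, np.inf))
                        if np.isfinite(lo):
                            draws = np.clip(draws, lo, hi)
                    else:
                        draws = _pmm_draw(sub, col, usable, config.pmm_donors,
                                          rng, sub_obs)
                    work.loc[np.flatnonzero(sel_miss), col] = draws
                imp_vals = _numeric_view(work.loc[miss_orig], col)
                trace_rows.append(
                    dict(imputation=mi, iteration=it, column=col,
                         mean=float(np.mean(imp_vals)), sd=float(np.std(imp_vals)))
                )
        tables.append(work)
    trace = pd.DataFrame(trace_rows)
    return ImputedStack(tables, predictor_matrix, methods, trace, missing_mask)


def rubin_pool(estimates: Sequence[float], variances: Sequence[float],
               df_complete: float | None = None) -> PooledEstimate:
    """Combine per-imputation estimates by Rubin's rules.

    Qbar = mean(estimates); W = mean(variances); B = sample variance of the
    estimates; T = W + (1 + 1/m) B.  Degrees of freedom follow Barnard-Rubin
    when ``df_complete`` is given, else the classic large-sample formula.
    """
    q = np.asarray(list(estimates), dtype=float)
    w = np.asarray(list(variances), dtype=float)
    if q.size == 0:
        raise ConfigurationError("need at least one imputation to pool")
    if q.shape != w.shape:
        raise ConfigurationError("estimates and variances must have equal length")
    if (w < 0).any():
        raise ConfigurationError("variances must be non-negative")
    m = q.size
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = wbar + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(t))
    if m == 1 or b == 0.0 or t == 0.0:
        df = np.inf if df_complete is None else float(df_complete)
    else:
        r = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / r**2
        if df_complete is None:
            df = df_old
        else:
            df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - r)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    if se > 0:
        tval = qbar / se
    else:
        tval = 0.0 if qbar == 0 else np.sign(qbar) * np.inf
    if np.isfinite(df):
        p = 2.0 * stats.t.sf(abs(tval), df)
        crit = float(stats.t.ppf(0.975, df))
    else:
        p = 2.0 * stats.norm.sf(abs(tval))
        crit = float(stats.norm.ppf(0.975))
    return PooledEstimate(
        estimate=qbar, within_var=wbar, between_var=b, total_var=t, se=se,
        df=float(df), t=float(tval), p=float(p),
        ci_low=qbar - crit * se, ci_high=qbar + crit * se, m=m,
    )


def aggregate_stack(stack: ImputedStack) -> pd.DataFrame:
    """Collapse the stack to one complete table for nonparametric stages.

    Originally missing numeric cells become the across-imputation mean
    rounded to the instrument grid; categorical cells the across-imputation
    mode (ties broken by first category order, logged).  Observed cells
    pass through unchanged.
    """
    base = stack.tables[0].copy()
    for col in stack.predictor_matrix.index:
        miss = stack.missing_mask[col]
        if not miss.any():
            continue
        if stack.methods[col] == "two-level-normal":
            vals = np.stack([t.loc[miss, col].to_numpy(dtype=float)
                             for t in stack.tables])
            mean = vals.mean(axis=0)
            lo, hi = INSTRUMENT_RANGES.get(col, (-np.inf, np.inf))
            if np.isfinite(lo):
                mean = np.clip(np.round(mean), lo, hi)
            base.loc[miss, col] = mean
        else:
            categories = list(pd.unique(stack.tables[0][col].dropna()))
            stacked = pd.DataFrame({i: t.loc[miss, col].reset_index(drop=True)
                                    for i, t in enumerate(stack.tables)})

            def _mode(row):
                counts = row.value_counts()
                top = counts.max()
                winners = [c for c in categories if counts.get(c, 0) == top]
                if len(winners) > 1:
                    logger.info("aggregation tie for %s broken by category order", col)
                return winners[0]

            base.loc[miss, col] = stacked.apply(_mode, axis=1).to_numpy()
    return base
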