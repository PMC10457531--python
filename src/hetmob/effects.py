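"""Average treatment effect, effect sizes, reliable change and moderation.

The average effect comes from a one-stage meta-analysis: post-test PHQ-9
regressed on the treatment indicator with the intercept and the baseline
adjustment stratified by trial, random {trial intercept, trial-by-treatment
slope}, estimated by maximum penalized likelihood with the Wishart prior.
Per-imputation treatment coefficients are pooled by Rubin's rules and
standardized to Cohen's d with the pooled observed baseline SD.

Also provided: the Jacobson-Truax reliable change index with an
across-imputation arm comparison, univariate treatment-by-moderator
interaction models (mixed-model and OLS/CR2 engines), and the percentile
change-score analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .imputation import ImputedStack, PooledEstimate, rubin_pool
from .penalized import WishartPrior, fit_mpl_lmm, fit_ols_cr2
from .synthetic import moderator_numeric

__all__ = [
    "EffectSize",
    "RCIConfig",
    "ModeratorResult",
    "PercentileTable",
    "ReliableChangeResult",
    "cohens_d",
    "estimate_ate",
    "reliable_change",
    "univariate_moderation",
    "percentile_change_analysis",
    "pooled_baseline_sd",
]

ATE_FIXED_TERMS = ("trial", "trial:phq9_baseline", "treatment")
ATE_RANDOM_TERMS = ("intercept", "treatment")


@dataclass
class EffectSize:
    """Standardized mean difference with its CI and raw-scale counterpart."""

    d: float
    ci_low: float
    ci_high: float
    beta: float
    sd_standardizer: float


@dataclass
class RCIConfig:
    """Reliable change index settings: PHQ-9 test-retest reliability (default
    0.84), the baseline SD used in the standard error of the difference, and
    the critical z (1.96)."""

    reliability: float = 0.84
    sd_baseline: float | None = None  # None: pooled baseline SD of the sample
    z_crit: float = 1.96

    def validate(self) -> None:
        if not (0.0 < self.reliability < 1.0):
            raise ConfigurationError("reliability must lie in (0, 1)")
        if self.sd_baseline is not None and self.sd_baseline <= 0:
            raise ConfigurationError("sd_baseline must be positive")
        if self.z_crit <= 0:
            raise ConfigurationError("z_crit must be positive")


@dataclass
class ReliableChangeResult:
    """Per-arm reliable improvement counts/rates and the pooled comparison."""

    se_diff: float
    threshold: float
    n_improved: dict[str, int]
    n_total: dict[str, int]
    rate_percent: dict[str, int]
    comparison: PooledEstimate

    def classification(self) -> pd.Series | None:
        return getattr(self, "_classification", None)


@dataclass
class ModeratorResult:
    """Pooled treatment-by-moderator interaction from univariate moderation."""

    moderator: str
    beta_interaction: float
    se: float
    t: float
    p: float
    tau2_intercept: float
    tau2_slope: float
    subgroup_effects: dict[str, EffectSize] | None = None


@dataclass
class PercentileTable:
    """Change scores by percentile band of a continuous moderator."""

    moderator: str
    bands: list[str]
    table: pd.DataFrame  # band x arm: n, mean_change, se
    heterogeneity_stat: float
    heterogeneity_p: float
    pairwise_p: pd.DataFrame


def pooled_baseline_sd(table: pd.DataFrame, column: str = "phq9_baseline") -> float:
    """Pooled (across arms) observed baseline SD: the default Cohen's d
    standardizer."""
    return float(table[column].std(ddof=1))


def cohens_d(beta: float, beta_ci: tuple[float, float], sd_standardizer: float) -> EffectSize:
    """Standardize a raw-scale adjusted difference: d = beta / sd, with the CI
    endpoints divided by the same SD.  Negative d favors the intervention
    (lower PHQ-9)."""
    if sd_standardizer <= 0:
        raise ConfigurationError("sd_standardizer must be positive")
    lo, hi = sorted(beta_ci)
    return EffectSize(
        d=beta / sd_standardizer,
        ci_low=lo / sd_standardizer,
        ci_high=hi / sd_standardizer,
        beta=beta,
        sd_standardizer=sd_standardizer,
    )


def estimate_ate(
    stack: ImputedStack,
    prior: WishartPrior | None = None,
) -> tuple[PooledEstimate, EffectSize]:
    """One-stage meta-analytic average treatment effect from an imputed stack.

    Fits the MPL mixed model per imputation, pools the treatment coefficient
    by Rubin's rules, and converts to Cohen's d using the pooled baseline SD
    of the first completed table.
    """
    prior = prior if prior is not None else WishartPrior()
    estimates, variances = [], []
    for t in stack.tables:
        fit = fit_mpl_lmm(t, "phq9_post", ATE_FIXED_TERMS, ATE_RANDOM_TERMS, prior=prior)
        estimates.append(fit.fixed_coefs["treatment"])
        variances.append(fit.fixed_se["treatment"] ** 2)
    pooled = rubin_pool(estimates, variances)
    sd = pooled_baseline_sd(stack.tables[0])
    effect = cohens_d(pooled.estimate, (pooled.ci_low, pooled.ci_high), sd)
    return pooled, effect


def reliable_change(
    table_or_stack: pd.DataFrame | ImputedStack,
    config: RCIConfig | None = None,
) -> ReliableChangeResult:
    """Jacobson-Truax reliable change classification and arm comparison.

    RC = (post - baseline) / SE_diff with SE_diff = sd_baseline *
    sqrt(2 (1 - reliability)); reliable improvement iff RC < -z_crit.
    The arm comparison is a linear-probability contrast of the improvement
    indicator on treatment, pooled across imputations by Rubin's rules
    (a z test for a single table).  Rates are reported as integer-rounded
    percentages alongside raw counts (counts/rates from the first completed
    table when a stack is given).
    """
    config = config or RCIConfig()
    config.validate()
    if isinstance(table_or_stack, ImputedStack):
        tables = table_or_stack.tables
    else:
        if table_or_stack["phq9_post"].isna().any():
            raise ConfigurationError(
                "phq9_post contains missing values; impute first or pass a stack"
            )
        tables = [table_or_stack]

    sd_b = config.sd_baseline
    if sd_b is None:
        sd_b = pooled_baseline_sd(tables[0])
    se_diff = sd_b * np.sqrt(2.0 * (1.0 - config.reliability))
    threshold = config.z_crit * se_diff

    estimates, variances = [], []
    first_class = None
    for t in tables:
        change = t["phq9_post"].to_numpy(dtype=float) - t["phq9_baseline"].to_numpy(dtype=float)
        rc = change / se_diff
        improved = rc < -config.z_crit
        if first_class is None:
            first_class = pd.Series(improved, index=t.index, name="reliable_improvement")
        treat = (t["arm"].astype(str) == "intervention").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(t)), treat])
        y = improved.astype(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / max(len(t) - 2, 1)
        var_b = s2 * np.linalg.inv(X.T @ X)[1, 1]
        estimates.append(beta[1])
        variances.append(var_b)
    comparison = rubin_pool(estimates, variances, df_complete=len(tables[0]) - 2)

    t0 = tables[0]
    change0 = t0["phq9_post"].to_numpy(dtype=float) - t0["phq9_baseline"].to_numpy(dtype=float)
    improved0 = change0 / se_diff < -config.z_crit
    arms = t0["arm"].astype(str)
    n_improved = {a: int(improved0[(arms == a).to_numpy()].sum())
                  for a in ("control", "intervention")}
    n_total = {a: int((arms == a).sum()) for a in ("control", "intervention")}
    rate = {a: int(round(100.0 * n_improved[a] / n_total[a])) if n_total[a] else 0
            for a in n_total}
    result = ReliableChangeResult(
        se_diff=float(se_diff),
        threshold=float(threshold),
        n_improved=n_improved,
        n_total=n_total,
        rate_percent=rate,
        comparison=comparison,
    )
    result._classification = first_class
    return result


def univariate_moderation(
    stack: ImputedStack,
    moderator: str,
    engine: Literal["mpl_lmm", "ols_cr2"] = "mpl_lmm",
    prior: WishartPrior | None = None,
    standardize: bool | None = None,
) -> ModeratorResult:
    """Pooled univariate treatment-by-moderator interaction.

    Model: phq9_post ~ trial-stratified intercept + trial-stratified baseline
    + treatment + moderator + treatment:moderator, with random {trial
    intercept, trial-by-treatment slope} for the mixed engine or CR2
    cluster-robust OLS for the sensitivity engine.  Continuous moderators
    are standardized so the interaction is on the per-SD scale; binary
    moderators stay 0/1 and additionally yield per-level subgroup effect
    sizes.
    """
    first = stack.tables[0]
    x0 = moderator_numeric(first, moderator)
    if np.nanstd(x0) == 0:
        raise ConfigurationError(f"moderator {moderator!r} is constant")
    binary = set(np.unique(x0[~np.isnan(x0)])) <= {0.0, 1.0}
    if standardize is None:
        standardize = not binary
    prior = prior if prior is not None else WishartPrior()

    inter_name = f"treatment:{moderator}__w"
    estimates, variances = [], []
    tau_i, tau_s = [], []
    sub_betas: dict[str, list[float]] = {"0": [], "1": []}
    sub_vars: dict[str, list[float]] = {"0": [], "1": []}
    for t in stack.tables:
        work = t.copy()
        x = moderator_numeric(work, moderator)
        if standardize:
            x = (x - x.mean()) / x.std()
        work[f"{moderator}__w"] = x
        terms = ["trial", "trial:phq9_baseline", "treatment",
                 f"{moderator}__w", f"treatment:{moderator}__w"]
        if moderator == "phq9_baseline":
            terms = ["trial", "trial:phq9_baseline", "treatment",
                     f"treatment:{moderator}__w"]
        if engine == "mpl_lmm":
            fit = fit_mpl_lmm(work, "phq9_post", terms, ATE_RANDOM_TERMS, prior=prior)
            var = fit.fixed_se[inter_name] ** 2
            tau_i.append(fit.tau2_intercept)
            tau_s.append(fit.tau2_slope)
        else:
            fit = fit_ols_cr2(work, "phq9_post", terms)
            var = fit.fixed_se[inter_name] ** 2
        estimates.append(fit.fixed_coefs[inter_name])
        variances.append(var)
        if binary:
            # per-level treatment effect: beta_treat (level 0) and
            # beta_treat + beta_interaction (level 1)
            b_t = fit.fixed_coefs["treatment"]
            b_i = fit.fixed_coefs[inter_name]
            names = fit.coef_names
            jt, ji = names.index("treatment"), names.index(inter_name)
            if hasattr(fit, "cov_beta"):
                cov = fit.cov_beta
            else:
                cov = fit.vcov
            sub_betas["0"].append(b_t)
            sub_vars["0"].append(cov[jt, jt])
            sub_betas["1"].append(b_t + b_i)
            sub_vars["1"].append(cov[jt, jt] + cov[ji, ji] + 2 * cov[jt, ji])

    if engine == "ols_cr2":
        df_c = fit.satterthwaite_df[fit.coef_names.index(inter_name)]
    else:
        df_c = None
    pooled = rubin_pool(estimates, variances, df_complete=df_c)
    sub_effects = None
    if binary:
        sd = pooled_baseline_sd(first)
        sub_effects = {}
        for lev in ("0", "1"):
            pe = rubin_pool(sub_betas[lev], sub_vars[lev])
            sub_effects[lev] = cohens_d(pe.estimate, (pe.ci_low, pe.ci_high), sd)
    return ModeratorResult(
        moderator=moderator,
        beta_interaction=pooled.estimate,
        se=pooled.se,
        t=pooled.t,
        p=pooled.p,
        tau2_intercept=float(np.mean(tau_i)) if tau_i else np.nan,
        tau2_slope=float(np.mean(tau_s)) if tau_s else np.nan,
        subgroup_effects=sub_effects,
    )


_BAND_LABELS = ["<20th", "20-40th", "40-60th", "60-80th", ">80th"]


def percentile_change_analysis(
    stack: ImputedStack,
    moderator: str,
) -> PercentileTable:
    """Change scores by quintile band of a continuous moderator.

    Bands use the pooled quantiles of the moderator in the first completed
    table; boundary values fall into the lower band (left-closed on the
    right edge).  Per band and arm: n, mean change (post - baseline), SE.
    The overall band-by-treatment interaction is an OLS F test; pairwise
    band contrasts compare the arm difference between bands.
    """
    first = stack.tables[0]
    x = moderator_numeric(first, moderator)
    if len(np.unique(x)) < 5:
        raise ConfigurationError(
            f"moderator {moderator!r} has fewer than 5 distinct values; "
            "treat it as categorical instead"
        )
    qs = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    # boundary values assigned to the lower band
    band_idx = np.searchsorted(qs, x, side="left")
    band_idx = np.clip(band_idx, 0, 4)

    # per-imputation change scores averaged across the stack
    changes = np.stack([
        t["phq9_post"].to_numpy(dtype=float) - t["phq9_baseline"].to_numpy(dtype=float)
        for t in stack.tables
    ])
    change = changes.mean(axis=0)
    arms = first["arm"].astype(str).to_numpy()

    rows = []
    for b in range(5):
        for arm in ("control", "intervention"):
            sel = (band_idx == b) & (arms == arm)
            vals = change[sel]
            rows.append(
                dict(band=_BAND_LABELS[b], arm=arm, n=int(sel.sum()),
                     mean_change=float(vals.mean()) if sel.any() else np.nan,
                     se=float(vals.std(ddof=1) / np.sqrt(sel.sum()))
                     if sel.sum() > 1 else np.nan)
            )
    table = pd.DataFrame(rows)

    # overall band x treatment interaction: F test comparing nested OLS models
    treat = (arms == "intervention").astype(float)
    B = np.eye(5)[band_idx]
    X_full = np.column_stack([B, treat[:, None] * B])
    X_null = np.column_stack([B, treat])
    stat, p = _nested_f(change, X_full, X_null)

    pair_p = pd.DataFrame(np.nan, index=_BAND_LABELS, columns=_BAND_LABELS)
    for a in range(5):
        for b in range(a + 1, 5):
            sel = (band_idx == a) | (band_idx == b)
            if sel.sum() < 4:
                continue
            grp = (band_idx[sel] == b).astype(float)
            Xf = np.column_stack([np.ones(sel.sum()), grp, treat[sel],
                                  grp * treat[sel]])
            Xn = Xf[:, :3]
            _, pv = _nested_f(change[sel], Xf, Xn)
            pair_p.iloc[a, b] = pair_p.iloc[b, a] = pv
    return PercentileTable(
        moderator=moderator,
        bands=list(_BAND_LABELS),
        table=table,
        heterogeneity_stat=float(stat),
        heterogeneity_p=float(p),
        pairwise_p=pair_p,
    )


def _nested_f(y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray) -> tuple[float, float]:
    n = len(y)
    bf, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    bn, *_ = np.linalg.lstsq(X_null, y, rcond=None)
    rss_f = float(np.sum((y - X_full @ bf) ** 2))
    rss_n = float(np.sum((y - X_null @ bn) ** 2))
    df1 = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_null)
    df2 = n - np.linalg.matrix_rank(X_full)
    if df1 <= 0 or df2 <= 0 or rss_f <= 0:
        return 0.0, 1.0
    f = ((rss_n - rss_f) / df1) / (rss_f / df2)
    return f, float(stats.f.sf(f, df1, df2))
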