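"""Synthetic two-trial individual-participant data with planted effect heterogeneity.

Emulates pooled data from two randomized trials of an Internet-based
depression intervention for chronic back-pain patients, plus a small
external pilot trial for transport testing.  Participants carry twenty
putative baseline moderators (sociodemographics, symptom-severity scales,
pain-related risk factors), a PHQ-9 post-test outcome with optional
missing-at-random dropout, and subgroup-specific treatment effects defined
by an ordered list of covariate predicates.

The generator is the test bed for every downstream stage: planted
conditional effects, between-trial heterogeneity and MAR missingness are
all recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "INSTRUMENT_RANGES",
    "MODERATORS",
    "CONTINUOUS_MODERATORS",
    "BINARY_MODERATORS",
    "POSITIVE_LEVEL",
    "SubgroupRule",
    "SyntheticConfig",
    "default_covariate_spec",
    "default_subgroup_rules",
    "generate_trial_pair",
    "apply_mar_missingness",
    "generate_external_trial",
    "moderator_numeric",
    "validate_participant_table",
]

# Admissible score ranges of the measurement instruments.
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "phq9_baseline": (0, 27),
    "phq9_post": (0, 27),
    "hamd_baseline": (0, 52),
    "nrs_pain": (0, 10),
    "aqol": (0, 100),
    "pseq": (0, 60),
    "spe": (0, 3),
    "odi": (0, 100),
    "internet_affinity": (0, 20),
    "age": (18, 99),
}

CONTINUOUS_MODERATORS: tuple[str, ...] = (
    "age",
    "internet_affinity",
    "phq9_baseline",
    "hamd_baseline",
    "nrs_pain",
    "aqol",
    "pseq",
    "spe",
    "odi",
)

BINARY_MODERATORS: tuple[str, ...] = (
    "gender",
    "relationship",
    "education",
    "children",
    "lifetime_scid",
    "prev_psychotherapy",
    "prev_dep_medication",
    "prev_pain_medication",
    "sick_leave",
    "social_support",
    "recruitment",
)

#: The a-priori moderator set, in canonical order.
MODERATORS: tuple[str, ...] = BINARY_MODERATORS[:2] + (
    "education",
    "children",
    "lifetime_scid",
    "prev_psychotherapy",
    "prev_dep_medication",
    "prev_pain_medication",
    "sick_leave",
    "social_support",
    "internet_affinity",
    "recruitment",
    "age",
    "phq9_baseline",
    "hamd_baseline",
    "nrs_pain",
    "aqol",
    "pseq",
    "spe",
    "odi",
)

#: Level of each binary moderator coded 1 when converting to numeric.
POSITIVE_LEVEL: dict[str, str] = {
    "gender": "female",
    "relationship": "yes",
    "education": ">13y",
    "children": "yes",
    "lifetime_scid": "yes",
    "prev_psychotherapy": "yes",
    "prev_dep_medication": "yes",
    "prev_pain_medication": "yes",
    "sick_leave": "yes",
    "social_support": "good",
    "recruitment": "online",
}

_NEGATIVE_LEVEL: dict[str, str] = {
    "gender": "male",
    "education": "<=13y",
    "social_support": "low",
    "recruitment": "onsite",
}


def default_covariate_spec() -> dict[str, dict]:
    """Baseline marginals of the pooled sample (means/SDs and category rates).

    Continuous scales are truncated normals rounded to the instrument grid;
    binary flags are Bernoulli draws with the pooled observed frequencies.
    """
    spec = {
        "age": {"dist": "truncnorm", "mean": 51.59, "sd": 8.55},
        "internet_affinity": {"dist": "truncnorm", "mean": 11.0, "sd": 3.5},
        # eligibility requires at least mild depressive symptoms at baseline
        "phq9_baseline": {"dist": "truncnorm", "mean": 10.06, "sd": 4.55, "low": 5},
        "hamd_baseline": {"dist": "truncnorm", "mean": 13.0, "sd": 5.0},
        "nrs_pain": {"dist": "truncnorm", "mean": 5.5, "sd": 1.8},
        "aqol": {"dist": "truncnorm", "mean": 45.0, "sd": 12.0},
        "pseq": {"dist": "truncnorm", "mean": 35.0, "sd": 12.0},
        "spe": {"dist": "truncnorm", "mean": 1.5, "sd": 0.9},
        "odi": {"dist": "truncnorm", "mean": 32.0, "sd": 13.0},
        "gender": {"dist": "bernoulli", "p": 0.6131},
        "relationship": {"dist": "bernoulli", "p": 0.7242},
        "education": {"dist": "bernoulli", "p": 0.4762},
        "children": {"dist": "bernoulli", "p": 0.7976},
        "lifetime_scid": {"dist": "bernoulli", "p": 0.4345},
        "prev_psychotherapy": {"dist": "bernoulli", "p": 0.3611},
        "prev_dep_medication": {"dist": "bernoulli", "p": 0.2817},
        "prev_pain_medication": {"dist": "bernoulli", "p": 0.6389},
        "sick_leave": {"dist": "bernoulli", "p": 0.6964},
        "social_support": {"dist": "bernoulli", "p": 0.3929},
        "recruitment": {"dist": "bernoulli", "p": 0.2937},
    }
    return spec


@dataclass(frozen=True)
class SubgroupRule:
    """One planted-subgroup definition: a vectorized covariate predicate and
    the standardized treatment effect d assigned to participants matching it."""

    label: str
    predicate: Callable[[pd.DataFrame], np.ndarray]
    d: float


def default_subgroup_rules() -> list[SubgroupRule]:
    """Planted heterogeneity mirroring the published six-subgroup tree:
    splits on baseline PHQ-9 (6 / 10 / 15), AQoL-6D (43) and PSEQ (38)."""
    return [
        SubgroupRule("phq9<=6", lambda t: t["phq9_baseline"].to_numpy() <= 6, -0.55),
        SubgroupRule(
            "6<phq9<=10, aqol<=43",
            lambda t: (t["phq9_baseline"].to_numpy() > 6)
            & (t["phq9_baseline"].to_numpy() <= 10)
            & (t["aqol"].to_numpy() <= 43),
            -0.44,
        ),
        SubgroupRule(
            "6<phq9<=10, aqol>43",
            lambda t: (t["phq9_baseline"].to_numpy() > 6)
            & (t["phq9_baseline"].to_numpy() <= 10)
            & (t["aqol"].to_numpy() > 43),
            -0.58,
        ),
        SubgroupRule(
            "10<phq9<=15, pseq<=38",
            lambda t: (t["phq9_baseline"].to_numpy() > 10)
            & (t["phq9_baseline"].to_numpy() <= 15)
            & (t["pseq"].to_numpy() <= 38),
            -1.31,
        ),
        SubgroupRule(
            "10<phq9<=15, pseq>38",
            lambda t: (t["phq9_baseline"].to_numpy() > 10)
            & (t["phq9_baseline"].to_numpy() <= 15)
            & (t["pseq"].to_numpy() > 38),
            0.24,
        ),
        SubgroupRule("phq9>15", lambda t: t["phq9_baseline"].to_numpy() > 15, -0.58),
    ]


def uniform_effect_rules(d: float) -> list[SubgroupRule]:
    """A single everyone-matches rule planting a homogeneous effect d."""
    return [SubgroupRule("all", lambda t: np.ones(len(t), dtype=bool), d)]


@dataclass
class SyntheticConfig:
    """Full specification of the synthetic study.

    Parameters
    ----------
    n_per_trial:
        Row counts of the two pooled trials.
    arm_allocation:
        Probability of assignment to the intervention arm.  Arm counts are
        produced by largest-remainder apportionment within trial so the
        pooled split is exact (default reproduces 253 intervention / 251
        control at N=504).
    covariate_spec:
        Marginal distribution of every moderator; see
        :func:`default_covariate_spec`.
    true_subgroup_rules:
        Ordered predicates planting subgroup-specific standardized effects.
        They must partition covariate space (checked at generation time).
    latent_loadings:
        Loadings of continuous scales on a shared latent severity factor,
        inducing realistic intercorrelation between PHQ-9, HAM-D, AQoL and
        PSEQ.
    baseline_slope, control_intercept:
        Linear outcome model: phq9_post = intercept + slope * phq9_baseline
        + trial deviations + arm * raw effect + noise.
    residual_sd:
        SD of the post-test noise in PHQ-9 points.
    effect_scale_sd:
        SD used to convert planted d values to raw PHQ-9 points (defaults to
        the configured baseline PHQ-9 SD so planted d values are recoverable
        with the pooled-baseline-SD standardizer).
    tau2_intercept, tau2_slope:
        Between-trial variances of the control mean and the raw treatment
        effect (squared PHQ-9 points).
    missing_rate, missing_logit_coefs:
        Marginal post-test missingness proportion and MAR dropout loadings
        (on raw covariate values; the logistic intercept is calibrated by
        bisection to hit the marginal rate).
    n_external:
        Size of the external validation trial.
    external_covariate_shift:
        Mapping column -> fixed value applied to the external trial (e.g.
        ``{"sick_leave": "yes"}``).
    """

    n_per_trial: tuple[int, int] = (252, 252)
    arm_allocation: float = 253 / 504
    covariate_spec: dict = field(default_factory=default_covariate_spec)
    true_subgroup_rules: list[SubgroupRule] = field(default_factory=default_subgroup_rules)
    latent_loadings: Mapping[str, float] = field(
        default_factory=lambda: {
            "phq9_baseline": 0.6,
            "hamd_baseline": 0.6,
            "aqol": -0.6,
            "pseq": -0.6,
        }
    )
    baseline_slope: float = 0.5
    control_intercept: float = 4.0
    residual_sd: float = 4.0
    effect_scale_sd: float | None = None
    tau2_intercept: float = 2.2
    tau2_slope: float = 0.48
    missing_rate: float = 0.20
    missing_logit_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"phq9_baseline": 0.15}
    )
    missing_logit_intercept: float | None = None
    n_external: int = 76
    external_covariate_shift: Mapping[str, object] | None = None
    seed: int = 0

    @property
    def d_scale_sd(self) -> float:
        if self.effect_scale_sd is not None:
            return float(self.effect_scale_sd)
        return float(self.covariate_spec["phq9_baseline"]["sd"])

    def validate(self) -> None:
        if not (0.0 <= self.arm_allocation <= 1.0):
            raise ConfigurationError("arm_allocation must be a probability")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if any(n <= 0 for n in self.n_per_trial):
            raise ConfigurationError("n_per_trial entries must be positive")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be positive")
        if self.tau2_intercept < 0 or self.tau2_slope < 0:
            raise ConfigurationError("between-trial variances must be non-negative")
        for name, spec in self.covariate_spec.items():
            if spec["dist"] == "bernoulli":
                if not (0.0 <= spec["p"] <= 1.0):
                    raise ConfigurationError(f"{name}: category probability outside [0,1]")
            elif spec["dist"] == "truncnorm":
                lo, hi = INSTRUMENT_RANGES.get(name, (-np.inf, np.inf))
                low = spec.get("low", lo)
                high = spec.get("high", hi)
                if low < lo or high > hi:
                    raise ConfigurationError(
                        f"{name}: configured range [{low}, {high}] exceeds the "
                        f"instrument range [{lo}, {hi}]"
                    )
                if spec["sd"] <= 0:
                    raise ConfigurationError(f"{name}: sd must be positive")
            else:  # pragma: no cover - defensive
                raise ConfigurationError(f"{name}: unknown distribution {spec['dist']!r}")
        if not self.true_subgroup_rules:
            raise ConfigurationError("true_subgroup_rules must be non-empty")


def _truncnorm_parent(mean: float, sd: float, low: float, high: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a truncated normal whose *truncated* mean/SD equal
    the configured values, found by root search (cached).  Falls back to the
    naive parameters when the targets are infeasible on the given support."""
    key = (round(mean, 6), round(sd, 6), round(low, 6), round(high, 6))
    if key in _PARENT_CACHE:
        return _PARENT_CACHE[key]
    from scipy import optimize as _opt
    from scipy import stats

    def moments(x):
        mu, log_sig = x
        sig = np.exp(log_sig)
        a, b = (low - mu) / sig, (high - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    try:
        sol = _opt.root(moments, x0=[mean, np.log(sd)], method="hybr")
        resid = moments(sol.x)
        if sol.success and max(abs(resid[0]), abs(resid[1])) < 1e-6:
            out = (float(sol.x[0]), float(np.exp(sol.x[1])))
        else:
            out = (mean, sd)
    except Exception:  # pragma: no cover - numerical fallback
        out = (mean, sd)
    _PARENT_CACHE[key] = out
    return out


_PARENT_CACHE: dict[tuple, tuple[float, float]] = {}


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per operation
    return np.random.default_rng([int(config.seed), stream])


def _apportion_arms(n: int, allocation: float, rng: np.random.Generator) -> np.ndarray:
    """Randomization-list style allocation: exact counts, shuffled order."""
    n_int = int(round(n * allocation))
    arms = np.array(["intervention"] * n_int + ["control"] * (n - n_int))
    rng.shuffle(arms)
    return arms


def _draw_covariates(config: SyntheticConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    from scipy import stats

    latent = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {}
    for name in MODERATORS:
        spec = config.covariate_spec[name]
        if spec["dist"] == "bernoulli":
            draws = rng.random(n) < spec["p"]
            pos = POSITIVE_LEVEL[name]
            neg = _NEGATIVE_LEVEL.get(name, "no")
            cols[name] = np.where(draws, pos, neg)
        else:
            lo, hi = INSTRUMENT_RANGES.get(name, (-np.inf, np.inf))
            low = spec.get("low", lo)
            high = spec.get("high", hi)
            loading = float(config.latent_loadings.get(name, 0.0))
            z = loading * latent + np.sqrt(max(0.0, 1.0 - loading**2)) * rng.standard_normal(n)
            # parent parameters chosen so the *truncated* marginal has the
            # configured mean/SD; the latent normal is mapped through the
            # truncated-normal quantile, preserving that marginal exactly
            mu, sig = _truncnorm_parent(spec["mean"], spec["sd"], low, high)
            a = (low - mu) / sig
            b = (high - mu) / sig
            u = stats.norm.cdf(z)
            vals = stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b,
                                       loc=mu, scale=sig)
            cols[name] = np.clip(np.round(vals), low, high)
    return pd.DataFrame(cols)


def _planted_d(table: pd.DataFrame, rules: Sequence[SubgroupRule]) -> np.ndarray:
    match = np.zeros(len(table), dtype=int)
    d = np.zeros(len(table))
    for rule in rules:
        mask = np.asarray(rule.predicate(table), dtype=bool)
        match += mask
        d = np.where(mask, rule.d, d)
    if (match != 1).any():
        bad = int((match != 1).sum())
        raise ConfigurationError(
            f"subgroup predicates do not partition covariate space: {bad} rows "
            "match zero or more than one rule"
        )
    return d


def _generate_single_trial(
    config: SyntheticConfig,
    n: int,
    trial: str,
    rng: np.random.Generator,
    intercept_dev: float,
    slope_dev: float,
    id_prefix: str,
) -> pd.DataFrame:
    covs = _draw_covariates(config, n, rng)
    if trial == "external" and config.external_covariate_shift:
        for col, value in config.external_covariate_shift.items():
            covs[col] = value
    arms = _apportion_arms(n, config.arm_allocation, rng)
    d = _planted_d(covs, config.true_subgroup_rules)
    treated = (arms == "intervention").astype(float)
    raw_effect = d * config.d_scale_sd + slope_dev
    mu = (
        config.control_intercept
        + intercept_dev
        + config.baseline_slope * covs["phq9_baseline"].to_numpy()
        + treated * raw_effect
    )
    post = mu + rng.normal(0.0, config.residual_sd, size=n)
    post = np.clip(np.round(post), *INSTRUMENT_RANGES["phq9_post"])
    out = pd.DataFrame(
        {
            "participant_id": [f"{id_prefix}-{i:04d}" for i in range(n)],
            "trial": trial,
            "arm": arms,
        }
    )
    out = pd.concat([out, covs], axis=1)
    out["phq9_post"] = post
    return out


def generate_trial_pair(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the pooled two-trial dataset (complete post-test outcome).

    Deterministic given ``config.seed``.  Between-trial deviations of the
    control mean and the raw treatment effect are drawn once per dataset
    from N(0, tau2).
    """
    config.validate()
    rng = _rng(config, 0)
    devs_int = rng.normal(0.0, np.sqrt(config.tau2_intercept), size=2)
    devs_slope = rng.normal(0.0, np.sqrt(config.tau2_slope), size=2)
    parts = []
    for k, (n, trial) in enumerate(zip(config.n_per_trial, ("trial_A", "trial_B"))):
        parts.append(
            _generate_single_trial(
                config, n, trial, rng, devs_int[k], devs_slope[k], trial[-1]
            )
        )
    table = pd.concat(parts, ignore_index=True)
    # largest-remainder pooled arm split: move rows between arms is not needed
    # because apportionment is done per trial with the pooled allocation; fix
    # any off-by-one at the pooled level deterministically
    n_total = len(table)
    target_int = int(round(config.arm_allocation * n_total))
    n_int = int((table["arm"] == "intervention").sum())
    if n_int != target_int:
        flip_to = "intervention" if n_int < target_int else "control"
        flip_from = "control" if flip_to == "intervention" else "intervention"
        idx = table.index[table["arm"] == flip_from][: abs(target_int - n_int)]
        table.loc[idx, "arm"] = flip_to
    return table


def generate_external_trial(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the external single-trial table (default n=76, trial="external").

    Drawn from the same structural model with its own trial-level deviation
    draws; ``external_covariate_shift`` can fix columns (e.g. everyone on
    sick leave) for transport testing.
    """
    config.validate()
    rng = _rng(config, 2)
    intercept_dev = rng.normal(0.0, np.sqrt(config.tau2_intercept))
    slope_dev = rng.normal(0.0, np.sqrt(config.tau2_slope))
    return _generate_single_trial(
        config, config.n_external, "external", rng, intercept_dev, slope_dev, "X"
    )


def moderator_numeric(table: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric view of a moderator column: binary flags become 0/1 indicators
    of their positive level, continuous scales pass through as floats."""
    col = table[name]
    if name in POSITIVE_LEVEL and not pd.api.types.is_numeric_dtype(col):
        return (col.astype(str) == POSITIVE_LEVEL[name]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def _missing_linear_predictor(table: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(table))
    for name, w in coefs.items():
        lp += float(w) * moderator_numeric(table, name)
    return lp


def apply_mar_missingness(table: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Mask phq9_post missing-at-random; returns a copy, input untouched.

    P(missing) = logistic(c + coefs . covariates) with the intercept c found
    by bisection so the expected marginal rate equals ``missing_rate``
    (unless ``missing_logit_intercept`` overrides it).  Only always-observed
    baseline columns enter the model, so the mechanism is MAR by
    construction.
    """
    from scipy.special import expit

    if not (0.0 <= config.missing_rate < 1.0):
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    out = table.copy()
    if config.missing_logit_intercept is None and config.missing_rate == 0.0:
        return out
    lp = _missing_linear_predictor(table, config.missing_logit_coefs)
    if config.missing_logit_intercept is not None:
        c = float(config.missing_logit_intercept)
    else:
        lo, hi = -50.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if expit(mid + lp).mean() < config.missing_rate:
                lo = mid
            else:
                hi = mid
        c = 0.5 * (lo + hi)
    rng = _rng(config, 1)
    mask = rng.random(len(table)) < expit(c + lp)
    out.loc[mask, "phq9_post"] = np.nan
    return out


def validate_participant_table(table: pd.DataFrame, require_post: bool = False) -> None:
    """Schema check for participant tables (user CSV input or generated)."""
    required = ["trial", "arm", *MODERATORS, "phq9_post"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ConfigurationError(f"missing required columns: {missing_cols}")
    if table["arm"].isna().any() or table["trial"].isna().any():
        raise ConfigurationError("trial and arm must never be missing")
    for name in CONTINUOUS_MODERATORS:
        lo, hi = INSTRUMENT_RANGES[name]
        vals = table[name].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise ConfigurationError(f"{name}: values outside instrument range [{lo}, {hi}]")
    if require_post and table["phq9_post"].isna().any():
        raise ConfigurationError("phq9_post contains missing values")


def config_with(config: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Convenience copy-with-changes for configs (dataclasses.replace wrapper)."""
    return replace(config, **kwargs)
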