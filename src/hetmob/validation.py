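"""Internal and external validation of fitted prediction procedures.

Apparent R-squared is 1 - SSE/SST.  Internal validation uses the bootstrap
bias-correction (optimism) approach: the procedure is refit on B bootstrap
resamples; the mean gap between each refit's performance on its own
resample and on the original data estimates the optimism, which is
subtracted from the apparent R-squared.  External validation applies the
frozen model to an unseen trial without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .mob import MOBTree, predict_tree

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationConfig",
    "ValidationReport",
    "r_squared",
    "bootstrap_bias_correct",
    "external_validate",
]


@dataclass
class ValidationConfig:
    """B=1000 bootstrap resamples by default; resampling at the participant
    level (optionally stratified by trial)."""

    n_boot: int = 1000
    seed: int = 0
    r2_definition: str = "one_minus_sse_over_sst"
    stratify_by_trial: bool = False
    max_failure_rate: float = 0.10

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")
        if self.r2_definition not in ("one_minus_sse_over_sst", "squared_correlation"):
            raise ConfigurationError(f"unknown r2_definition {self.r2_definition!r}")


@dataclass
class ValidationReport:
    """Apparent, optimism-corrected and (optionally) external R-squared."""

    r2_apparent: float
    optimism: float
    r2_adjusted: float
    n_boot_used: int
    failures: int
    r2_external: float | None = None


def r_squared(predicted: np.ndarray, observed: np.ndarray,
              definition: str = "one_minus_sse_over_sst") -> float:
    """Proportion of outcome variation explained: 1 - SSE/SST (may be
    negative for predictors worse than the mean), or the squared Pearson
    correlation under the alternative definition."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ConfigurationError("predicted and observed must be equal-length vectors")
    if len(observed) < 2:
        raise ConfigurationError("need at least two observations")
    sst = float(((observed - observed.mean()) ** 2).sum())
    if sst == 0:
        raise ConfigurationError("observed vector is constant; R^2 undefined")
    if definition == "squared_correlation":
        if predicted.std() == 0:
            return 0.0
        return float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    sse = float(((observed - predicted) ** 2).sum())
    return 1.0 - sse / sst


def bootstrap_bias_correct(
    table: pd.DataFrame,
    fit_procedure: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    config: ValidationConfig | None = None,
    outcome: str = "phq9_post",
) -> ValidationReport:
    """Optimism-corrected performance of a fit procedure.

    ``fit_procedure(table)`` must return a predictor mapping a table to a
    prediction vector; the whole adaptive pipeline being validated (e.g.
    tree growth) belongs inside it.  Per resample b: refit, compute R^2 on
    the resample and on the original table; optimism is the mean of the
    differences.  Deterministic given the seed; errors in more than
    ``max_failure_rate`` of the refits abort (unstable procedure), failed
    refits are excluded and logged.
    """
    config = config or ValidationConfig()
    config.validate()
    table = table.reset_index(drop=True)
    y = table[outcome].to_numpy(dtype=float)
    predictor = fit_procedure(table)
    r2_app = r_squared(predictor(table), y, config.r2_definition)
    rng = np.random.default_rng([int(config.seed), 29])
    n = len(table)
    optimisms = []
    failures = 0
    groups = table["trial"].astype(str).to_numpy() if config.stratify_by_trial else None
    for _ in range(config.n_boot):
        if groups is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.concatenate([
                rng.choice(np.flatnonzero(groups == g),
                           size=int((groups == g).sum()), replace=True)
                for g in np.unique(groups)
            ])
        boot = table.iloc[idx].reset_index(drop=True)
        try:
            pred_b = fit_procedure(boot)
            r2_boot = r_squared(pred_b(boot), y[idx], config.r2_definition)
            r2_orig = r_squared(pred_b(table), y, config.r2_definition)
        except Exception as exc:  # refit failed on this resample
            failures += 1
            logger.warning("bootstrap refit failed: %s", exc)
            if failures > config.max_failure_rate * config.n_boot:
                raise ConfigurationError(
                    "more than {:.0%} of bootstrap refits failed; the "
                    "procedure is too unstable to validate".format(config.max_failure_rate)
                ) from exc
            continue
        optimisms.append(r2_boot - r2_orig)
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return ValidationReport(
        r2_apparent=float(r2_app),
        optimism=optimism,
        r2_adjusted=float(r2_app - optimism),
        n_boot_used=len(optimisms),
        failures=failures,
    )


def external_validate(tree: MOBTree, external: pd.DataFrame,
                      outcome: str = "phq9_post",
                      definition: str = "one_minus_sse_over_sst") -> float:
    """R-squared of the frozen tree's predictions on an unseen trial."""
    if external[outcome].isna().any():
        raise ConfigurationError("external table must have a complete outcome")
    preds = predict_tree(tree, external)["prediction"].to_numpy()
    return r_squared(preds, external[outcome].to_numpy(dtype=float), definition)
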