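"""End-to-end orchestration of the moderation analysis.

Stages (in dependency order): simulate (or load a user CSV) -> impute ->
average treatment effect -> univariate moderation -> forest preselection ->
MOB tree -> internal/external validation.  Every stage can be toggled; the
result is an :class:`AnalysisReport` that serializes to JSON plus
human-readable tables, fully reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .effects import (RCIConfig, estimate_ate, percentile_change_analysis,
                      reliable_change, univariate_moderation)
from .exceptions import ConfigurationError
from .forest import (ForestConfig, grow_forest, permutation_importance,
                     select_partitioning_variables)
from .imputation import ImputationConfig, aggregate_stack, impute
from .mob import MOBControl, MOBTree, grow_mob_tree, predict_tree
from .synthetic import (MODERATORS, SyntheticConfig, apply_mar_missingness,
                        generate_external_trial, generate_trial_pair,
                        validate_participant_table)
from .validation import (ValidationConfig, bootstrap_bias_correct,
                         external_validate)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "percent",
           "report_node_summary", "tree_to_dict", "tree_to_dot"]


def percent(count: int, total: int, decimals: int = 1) -> float | int:
    """Reporting arithmetic for printed proportions: 100*count/total rounded
    to the requested precision (integer when decimals=0, as used for
    reliable-improvement rates)."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    value = round(100.0 * count / total, decimals)
    return int(value) if decimals == 0 else value


@dataclass
class PipelineConfig:
    """Composite configuration of all stages plus toggles and IO paths."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    mob: MOBControl = field(default_factory=MOBControl)
    forest: ForestConfig = field(default_factory=ForestConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    rci: RCIConfig = field(default_factory=RCIConfig)
    moderators: list[str] = field(default_factory=lambda: list(MODERATORS))
    stages: dict[str, bool] = field(default_factory=lambda: {
        "impute": True, "ate": True, "moderators": True, "forest": True,
        "tree": True, "validate": True,
    })
    input_csv: str | None = None
    external_csv: str | None = None
    out_dir: str | None = None
    seed: int = 0

    def reseed(self) -> None:
        """Propagate the global seed into every stage seed."""
        self.synthetic.seed = self.seed
        self.imputation.seed = self.seed + 1
        self.forest.seed = self.seed + 2
        self.validation.seed = self.seed + 3


@dataclass
class AnalysisReport:
    """All result surfaces of one pipeline run."""

    ate: dict | None = None
    reliable_change: dict | None = None
    moderator_table: pd.DataFrame | None = None
    percentile_table: pd.DataFrame | None = None
    importance: pd.DataFrame | None = None
    selected_moderators: list[str] | None = None
    tree: MOBTree | None = None
    node_summary: pd.DataFrame | None = None
    validation: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = dict(provenance=self.provenance)
        if self.ate is not None:
            out["ate"] = self.ate
        if self.reliable_change is not None:
            out["reliable_change"] = self.reliable_change
        if self.moderator_table is not None:
            out["moderator_table"] = self.moderator_table.to_dict(orient="records")
        if self.percentile_table is not None:
            out["percentile_table"] = self.percentile_table.to_dict(orient="records")
        if self.importance is not None:
            out["importance"] = self.importance.to_dict(orient="records")
        if self.selected_moderators is not None:
            out["selected_moderators"] = self.selected_moderators
        if self.tree is not None:
            out["tree"] = tree_to_dict(self.tree)
        if self.node_summary is not None:
            out["node_summary"] = self.node_summary.to_dict(orient="records")
        if self.validation is not None:
            out["validation"] = self.validation
        return out


def report_node_summary(tree: MOBTree, total_n: int | None = None) -> pd.DataFrame:
    """Terminal-node report: n, percent of sample (one decimal), d_i with CI
    (two decimals) and reliable-improvement rates (integer percent)."""
    total_n = total_n or tree.n_train
    if total_n < sum(n.n for n in tree.terminal_nodes()):
        raise ConfigurationError("total_n smaller than the sum of node sizes")
    rows = []
    for node in sorted(tree.terminal_nodes(), key=lambda nd: nd.node_id):
        row = dict(
            node=node.node_id,
            n=node.n,
            percent=percent(node.n, total_n, 1),
            d=round(node.effect.d, 2) if node.effect else None,
            ci_low=round(node.effect.ci_low, 2) if node.effect else None,
            ci_high=round(node.effect.ci_high, 2) if node.effect else None,
        )
        if node.improvement:
            for arm in ("control", "intervention"):
                row[f"improved_{arm}"] = node.improvement["n_improved"].get(arm)
                row[f"improved_{arm}_pct"] = node.improvement["rate_percent"].get(arm)
            row["improvement_p"] = node.improvement["p"]
        rows.append(row)
    return pd.DataFrame(rows)


def tree_to_dict(tree: MOBTree) -> dict:
    """Machine-readable nested representation of the fitted tree."""

    def rec(node):
        if node.is_terminal:
            return dict(
                id=node.node_id, n=node.n, terminal=True,
                percent=node.percent_of_sample,
                coefs=dict(intercept=float(node.model.beta[0]),
                           treatment=float(node.model.beta[1])),
                d=node.effect.d if node.effect else None,
                ci=[node.effect.ci_low, node.effect.ci_high] if node.effect else None,
            )
        d = dict(id=node.node_id, n=node.n, terminal=False,
                 split_variable=node.split_variable,
                 p_adjusted=node.p_adjusted)
        if node.left_categories is not None:
            d["left_categories"] = sorted(node.left_categories)
        else:
            d["cutpoint"] = node.cutpoint
        d["left"] = rec(node.left)
        d["right"] = rec(node.right)
        return d

    return rec(tree.root)


def tree_to_dot(tree: MOBTree) -> str:
    """Graphviz DOT export with terminal-node effect labels."""
    lines = ["digraph mobtree {", '  node [shape=box, fontsize=10];']

    def rec(node):
        if node.is_terminal:
            lab = f"node {node.node_id}\\nn={node.n} ({node.percent_of_sample:.1f}%)"
            if node.effect:
                lab += f"\\nd={node.effect.d:.2f} " \
                       f"[{node.effect.ci_low:.2f}, {node.effect.ci_high:.2f}]"
            lines.append(f'  n{node.node_id} [label="{lab}", style=rounded];')
            return
        if node.left_categories is not None:
            cond = "{" + ",".join(sorted(node.left_categories)) + "}"
        else:
            cond = f"<= {node.cutpoint:g}"
        lines.append(
            f'  n{node.node_id} [label="{node.split_variable}\\n'
            f'p={node.p_adjusted:.3g}"];'
        )
        rec(node.left)
        rec(node.right)
        lines.append(f'  n{node.node_id} -> n{node.left.node_id} [label="{cond}"];')
        lines.append(f'  n{node.node_id} -> n{node.right.node_id} [label="else"];')

    rec(tree.root)
    lines.append("}")
    return "\n".join(lines)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if callable(o):
            return getattr(o, "__name__", "callable")
        return str(o)

    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_csv(path: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_participant_table(table)
    return table


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the enabled stages in dependency order.

    Uses synthetic data (generated from ``config.synthetic``) unless
    ``input_csv`` points at a participant table.  Raises on the first stage
    failure, naming the stage; artifacts produced so far are kept on the
    report object attached to the exception where possible.
    """
    config.reseed()
    report = AnalysisReport()
    t_start = time.time()
    stage = "simulate"
    timings: dict[str, float] = {}
    try:
        t0 = time.time()
        if config.input_csv:
            table = _load_csv(config.input_csv)
        else:
            table = generate_trial_pair(config.synthetic)
            table = apply_mar_missingness(table, config.synthetic)
        external = None
        if config.external_csv:
            external = _load_csv(config.external_csv)
        elif not config.input_csv:
            external = generate_external_trial(config.synthetic)
        timings[stage] = time.time() - t0

        stage = "impute"
        t0 = time.time()
        if config.stages.get("impute", True):
            stack = impute(table, config.imputation)
        else:
            if table["phq9_post"].isna().any():
                raise ConfigurationError(
                    "imputation disabled but phq9_post has missing values"
                )
            stack = impute(table, ImputationConfig(m=1, seed=config.seed))
        agg = aggregate_stack(stack)
        timings[stage] = time.time() - t0

        stage = "ate"
        if config.stages.get("ate", True):
            t0 = time.time()
            pooled, effect = estimate_ate(stack)
            rc = reliable_change(stack, config.rci)
            report.ate = dict(
                beta=pooled.estimate, se=pooled.se, t=pooled.t, p=pooled.p,
                ci=[pooled.ci_low, pooled.ci_high],
                d=effect.d, d_ci=[effect.ci_low, effect.ci_high],
                sd_standardizer=effect.sd_standardizer, m=pooled.m,
            )
            report.reliable_change = dict(
                se_diff=rc.se_diff, threshold=rc.threshold,
                n_improved=rc.n_improved, n_total=rc.n_total,
                rate_percent=rc.rate_percent, p=rc.comparison.p,
            )
            timings[stage] = time.time() - t0

        stage = "moderators"
        uni_results = []
        if config.stages.get("moderators", True):
            t0 = time.time()
            rows = []
            for mod in config.moderators:
                res = univariate_moderation(stack, mod)
                uni_results.append(res)
                rows.append(dict(
                    moderator=mod, beta=res.beta_interaction, se=res.se,
                    t=res.t, p=res.p, tau2_intercept=res.tau2_intercept,
                    tau2_slope=res.tau2_slope,
                ))
            report.moderator_table = pd.DataFrame(rows)
            # change scores by quintile of baseline severity
            pct = percentile_change_analysis(stack, "phq9_baseline")
            pt = pct.table.copy()
            pt.attrs["heterogeneity_p"] = pct.heterogeneity_p
            report.percentile_table = pt
            timings[stage] = time.time() - t0

        stage = "forest"
        if config.stages.get("forest", True):
            t0 = time.time()
            forest = grow_forest(agg, config.moderators, config.forest)
            imp = permutation_importance(forest, agg)
            report.importance = imp.table
            if uni_results:
                selected = select_partitioning_variables(imp, uni_results)
            else:
                selected = imp.positive()
            report.selected_moderators = selected
            timings[stage] = time.time() - t0
        else:
            report.selected_moderators = list(config.moderators)
            report.provenance["preselection"] = "skipped"

        stage = "tree"
        if config.stages.get("tree", True):
            t0 = time.time()
            part_vars = report.selected_moderators or list(config.moderators)
            tree = grow_mob_tree(agg, part_vars, config.mob, rci_config=config.rci)
            report.tree = tree
            report.node_summary = report_node_summary(tree)
            timings[stage] = time.time() - t0

        stage = "validate"
        if config.stages.get("validate", True) and report.tree is not None:
            t0 = time.time()
            part_vars = report.selected_moderators or list(config.moderators)

            def proc(t):
                tr = grow_mob_tree(t, part_vars, config.mob, rci_config=config.rci)
                return lambda tt: predict_tree(tr, tt)["prediction"].to_numpy()

            val = bootstrap_bias_correct(agg, proc, config.validation)
            result = dict(
                r2_apparent=val.r2_apparent, optimism=val.optimism,
                r2_adjusted=val.r2_adjusted, n_boot=val.n_boot_used,
                failures=val.failures,
            )
            if external is not None:
                result["r2_external"] = external_validate(report.tree, external)
            report.validation = result
            timings[stage] = time.time() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.provenance.update(
        config_hash=_config_hash(config),
        seed=config.seed,
        version=_version,
        runtime_s=round(time.time() - t_start, 2),
        stage_timings={k: round(v, 2) for k, v in timings.items()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report.to_json_dict(), indent=2, default=_json_default)
        )
        if report.moderator_table is not None:
            report.moderator_table.to_csv(out / "moderator_table.csv", index=False)
        if report.importance is not None:
            report.importance.to_csv(out / "importance.csv", index=False)
        if report.node_summary is not None:
            report.node_summary.to_csv(out / "node_summary.csv", index=False)
        if report.tree is not None:
            (out / "tree.dot").write_text(tree_to_dot(report.tree))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    return str(o)
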