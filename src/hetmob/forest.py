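"""Model-based random forest for moderator preselection.

An ensemble of MOB trees grown on bootstrap resamples of the aggregated
table, each offered a random third of the candidate moderators as
partitioning variables.  Permutation importance is the mean out-of-bag
increase in node-model negative log-likelihood after permuting a
moderator's out-of-bag values (one permutation per tree, seeded; negative
values possible and preserved).  The preselection rule keeps moderators
with positive importance and/or a significant univariate interaction.

Forests run without the random-effects alternation: they operate on the
aggregated imputed dataset, where trial enters the downstream tree stage
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import ModeratorResult
from .exceptions import ConfigurationError
from .mob import MOBControl, MOBTree, _assignments_fast, grow_mob_tree

__all__ = [
    "ForestConfig",
    "ModelForest",
    "ImportanceTable",
    "grow_forest",
    "permutation_importance",
    "select_partitioning_variables",
]


def _forest_control() -> MOBControl:
    # trees inside forests skip the global random-effects stage and use a
    # lighter simulated supLM reference
    return MOBControl(mixed_effects=False, n_null_paths=2000)


@dataclass
class ForestConfig:
    """Forest settings: 300 trees, one third of the moderators per tree,
    bootstrap resampling with out-of-bag tracking."""

    n_trees: int = 300
    mtry_fraction: float = 1.0 / 3.0
    bootstrap: bool = True
    control: MOBControl = field(default_factory=_forest_control)
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not (0.0 < self.mtry_fraction <= 1.0):
            raise ConfigurationError("mtry_fraction must lie in (0, 1]")


@dataclass
class ModelForest:
    """A grown forest: per tree the fitted MOB tree, its candidate moderators
    and its out-of-bag row positions."""

    trees: list[MOBTree]
    candidates: list[list[str]]
    oob_indices: list[np.ndarray]
    moderators: list[str]
    config: ForestConfig
    fingerprint: int
    outcome: str = "phq9_post"


@dataclass
class ImportanceTable:
    """Permutation importances and the derived selection flags."""

    table: pd.DataFrame  # moderator, importance, n_trees_candidate

    def positive(self) -> list[str]:
        t = self.table
        return list(t.loc[t["importance"] > 0, "moderator"])


def grow_forest(
    table: pd.DataFrame,
    moderators: Sequence[str],
    config: ForestConfig | None = None,
    outcome: str = "phq9_post",
) -> ModelForest:
    """Grow the forest on a complete table; deterministic given the seed."""
    config = config or ForestConfig()
    config.validate()
    if table[list(moderators) + [outcome]].isna().any().any():
        raise ConfigurationError("forest requires complete data; aggregate first")
    table = table.reset_index(drop=True)
    n = len(table)
    mtry = int(np.ceil(config.mtry_fraction * len(moderators)))
    rng = np.random.default_rng([int(config.seed), 11])
    trees, cands, oobs = [], [], []
    for _ in range(config.n_trees):
        if config.bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = rng.permutation(n)[: int(0.632 * n)]
        oob = np.setdiff1d(np.arange(n), np.unique(idx))
        cand = list(rng.choice(list(moderators), size=mtry, replace=False))
        sub = table.iloc[idx].reset_index(drop=True)
        tree = grow_mob_tree(sub, cand, control=config.control, outcome=outcome)
        trees.append(tree)
        cands.append(cand)
        oobs.append(oob)
    fp = int(pd.util.hash_pandas_object(table, index=False).sum() % (2**63))
    return ModelForest(trees, cands, oobs, list(moderators), config, fp,
                       outcome=outcome)


def _tree_oob_nll(tree: MOBTree, table: pd.DataFrame, y: np.ndarray) -> float:
    """Mean Gaussian node-model negative log-likelihood on the given rows."""
    assign = _assignments_fast(tree.root, table.reset_index(drop=True))
    treat = (table["arm"].astype(str) == "intervention").to_numpy(dtype=float)
    nll = np.empty(len(table))
    models = {node.node_id: node.model for node in tree.terminal_nodes()}
    for nid in np.unique(assign):
        m = models[nid]
        sel = assign == nid
        pred = m.beta[0] + m.beta[1] * treat[sel]
        nll[sel] = 0.5 * np.log(2 * np.pi * m.sigma2) + (y[sel] - pred) ** 2 / (
            2 * m.sigma2
        )
    return float(nll.mean())


def permutation_importance(forest: ModelForest, table: pd.DataFrame) -> ImportanceTable:
    """Out-of-bag permutation importance per moderator.

    For every tree where the moderator was a candidate: evaluate the
    out-of-bag mean negative log-likelihood before and after permuting the
    moderator's out-of-bag values (one permutation per tree).  The
    importance is the mean difference across those trees; a moderator never
    used in any split has importance exactly 0.
    """
    table = table.reset_index(drop=True)
    fp = int(pd.util.hash_pandas_object(table, index=False).sum() % (2**63))
    if fp != forest.fingerprint:
        raise ConfigurationError("forest was grown on a different table")
    y = table[forest.outcome].to_numpy(dtype=float)
    rng = np.random.default_rng([int(forest.config.seed), 13])
    sums = {v: 0.0 for v in forest.moderators}
    counts = {v: 0 for v in forest.moderators}
    for tree, cand, oob in zip(forest.trees, forest.candidates, forest.oob_indices):
        if len(oob) == 0:
            continue
        sub = table.iloc[oob].reset_index(drop=True)
        base_nll = _tree_oob_nll(tree, sub, y[oob])
        split_vars = set()

        def collect(node):
            if not node.is_terminal:
                split_vars.add(node.split_variable)
                collect(node.left)
                collect(node.right)

        collect(tree.root)
        perm = rng.permutation(len(oob))
        for v in cand:
            counts[v] += 1
            if v not in split_vars:
                continue  # permutation cannot change predictions
            pert = sub.copy()
            pert[v] = sub[v].to_numpy()[perm]
            sums[v] += _tree_oob_nll(tree, pert, y[oob]) - base_nll
    rows = [
        dict(moderator=v,
             importance=sums[v] / counts[v] if counts[v] else 0.0,
             n_trees_candidate=counts[v])
        for v in forest.moderators
    ]
    return ImportanceTable(pd.DataFrame(rows))


def select_partitioning_variables(
    importance: ImportanceTable,
    univariate: Sequence[ModeratorResult],
    alpha: float = 0.05,
) -> list[str]:
    """Preselection rule: positive permutation importance and/or significant
    univariate interaction (p < alpha)."""
    imp = importance.table.set_index("moderator")["importance"]
    uni = {r.moderator: r.p for r in univariate}
    mismatch = set(imp.index).symmetric_difference(uni)
    if mismatch:
        raise ConfigurationError(
            f"moderator sets differ between inputs: {sorted(mismatch)}"
        )
    return [v for v in imp.index if imp[v] > 0 or uni[v] < alpha]
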