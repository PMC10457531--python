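"""Model-based recursive partitioning with a treatment-effect node model.

Each tree node holds a Gaussian working model (intercept + treatment
indicator).  Candidate partitioning variables are screened by parameter-
instability tests on the per-observation score matrix: a supLM test over
the ordered-variable split fractions, a chi-square test across categories
for categorical variables.  Bonferroni-corrected p-values below alpha
trigger an exhaustive cutpoint search minimizing the summed child residual
sum of squares; recursion continues until no variable is unstable or the
minimum node size binds (pre-pruning).

Trial-level structure is handled by an alternating scheme: a global
multilevel model (random trial intercept + trial-by-treatment slope, MPL
estimation with the Wishart prior) is estimated given the current
tree-implied fixed structure, the tree is re-grown on the outcome minus the
predicted random-effect contribution, and the two steps repeat until node
assignments stabilize.  With only two trials this keeps score-based tests
well-defined where per-node mixed fits would be unstable.

supLM p-values come from simulating the limiting Brownian-bridge supremum
at the admissible split fractions (fixed internal seed, cached); a
Miller-Siegmund style crossing-probability approximation is available as a
cross-check for single-parameter processes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectSize, RCIConfig, cohens_d, pooled_baseline_sd
from .exceptions import ConfigurationError
from .penalized import WishartPrior, mpl_lmm_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "MOBControl",
    "MOBNode",
    "MOBTree",
    "NodeModel",
    "fit_node_model",
    "node_scores",
    "suplm_test",
    "suplm_pvalue_crossing",
    "cat_instability_test",
    "select_split_variable",
    "search_cutpoint",
    "grow_mob_tree",
    "predict_tree",
]


@dataclass
class MOBControl:
    """Stopping and estimation controls for tree growth.

    alpha=0.05 with Bonferroni correction (pre-pruning), at least 20
    observations per node, optional depth cap.  ``mixed_effects`` switches
    the alternating global random-effects scheme on (trees) or off
    (forests, which run on the aggregated table).  ``n_null_paths`` and
    ``null_seed`` control the simulated supLM reference distribution.
    """

    alpha: float = 0.05
    bonferroni: bool = True
    min_node_size: int = 20
    max_depth: int | None = None
    mixed_effects: bool = True
    max_cycles: int = 50
    n_null_paths: int = 10_000
    null_seed: int = 20160928
    prior: WishartPrior = field(default_factory=WishartPrior)

    def validate(self, n_params: int = 2) -> None:
        # alpha = 1 disables pre-pruning entirely (saturated growth down to
        # min_node_size; split variable chosen by instability statistic)
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.min_node_size < n_params + 1:
            raise ConfigurationError(
                "min_node_size must be at least the number of node-model "
                f"parameters + 1 (= {n_params + 1})"
            )


@dataclass
class NodeModel:
    """Gaussian working model of one node: y ~ intercept + treatment."""

    beta: np.ndarray  # (intercept, treatment)
    sigma2: float
    n: int
    sse: float
    cov_beta: np.ndarray

    @property
    def loglik(self) -> float:
        return -0.5 * self.n * (np.log(2 * np.pi * self.sigma2) + 1.0)


def _node_design(table: pd.DataFrame) -> np.ndarray:
    treat = (table["arm"].astype(str) == "intervention").to_numpy(dtype=float)
    return np.column_stack([np.ones(len(table)), treat])


def fit_node_model(table: pd.DataFrame, outcome: str = "phq9_post") -> NodeModel:
    """OLS fit of the node model on exactly the rows of ``table``."""
    X = _node_design(table)
    y = table[outcome].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    n = len(y)
    sigma2 = max(sse / n, 1e-12)
    cov = sse / max(n - 2, 1) * np.linalg.pinv(X.T @ X)
    return NodeModel(beta=beta, sigma2=sigma2, n=n, sse=sse, cov_beta=cov)


def node_scores(fit: NodeModel, table: pd.DataFrame, outcome: str = "phq9_post") -> np.ndarray:
    """Per-observation estimating-function contributions at the node fit.

    Row i is the gradient of observation i's Gaussian log-likelihood with
    respect to (intercept, treatment coefficient): x_i * residual_i /
    sigma2.  Columns sum to ~0 at the optimum.
    """
    X = _node_design(table)
    if fit.n != len(table):
        raise ConfigurationError("fit and table cover different rows")
    y = table[outcome].to_numpy(dtype=float)
    resid = y - X @ fit.beta
    return X * (resid / fit.sigma2)[:, None]


# ---------------------------------------------------------------------------
# parameter-instability tests

_NULL_CACHE: dict[tuple, np.ndarray] = {}


def _suplm_null_distribution(
    k: int, fracs: np.ndarray, n_paths: int, seed: int
) -> np.ndarray:
    """Simulated null distribution of sup_t ||BB(t)||^2 / (t(1-t)) over the
    given split fractions, BB a k-dimensional Brownian bridge."""
    key = (k, n_paths, seed, np.round(fracs, 6).tobytes())
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(seed)
    grid = np.concatenate([fracs, [1.0]])
    dt = np.diff(np.concatenate([[0.0], grid]))
    maxima = np.zeros(n_paths)
    # chunked simulation keeps memory bounded for long grids
    chunk = max(1, int(2e7 // (len(grid) * k)))
    done = 0
    while done < n_paths:
        b = min(chunk, n_paths - done)
        incr = rng.standard_normal((b, len(grid), k)) * np.sqrt(dt)[None, :, None]
        bm = np.cumsum(incr, axis=1)
        bridge = bm[:, :-1, :] - fracs[None, :, None] * bm[:, -1:, :]
        lm = (bridge**2).sum(axis=2) / (fracs * (1.0 - fracs))[None, :]
        maxima[done:done + b] = lm.max(axis=1)
        done += b
    _NULL_CACHE[key] = maxima
    return maxima


def suplm_pvalue_crossing(stat: float, a: float, b: float) -> float:
    """Miller-Siegmund / DeLong crossing-probability approximation to the
    supLM tail for a single-parameter (k=1) score process over [a, b];
    used as an independent cross-check of the simulated reference."""
    if stat <= 0:
        return 1.0
    x = float(np.sqrt(stat))
    logratio = np.log((b * (1.0 - a)) / (a * (1.0 - b)))
    phi = float(stats.norm.pdf(x))
    p = phi * ((x - 1.0 / x) * logratio + 4.0 / x)
    return float(min(1.0, max(0.0, p)))


def suplm_test(
    scores: np.ndarray,
    z: np.ndarray,
    min_node_size: int = 20,
    n_paths: int = 10_000,
    seed: int = 20160928,
) -> tuple[float, float]:
    """supLM parameter-instability test along an ordered variable.

    Observations are sorted by z; the cumulative score process is
    standardized by the root information; the statistic is the maximum LM
    statistic ||W(t)||^2 / (t(1-t)) over admissible split fractions
    (candidates at distinct-value boundaries leaving at least
    ``min_node_size`` observations on each side).  The p-value is the
    exceedance rate in the simulated Brownian-bridge reference (fixed
    internal seed, cached by grid).
    """
    scores = np.asarray(scores, dtype=float)
    z = np.asarray(z)
    n, k = scores.shape
    if len(z) != n:
        raise ConfigurationError("scores and z have different lengths")
    if len(np.unique(z)) < 2:
        warnings.warn("constant partitioning variable; no instability testable")
        return 0.0, 1.0
    order = np.argsort(z, kind="stable")
    zs = z[order]
    s = scores[order]
    J = (s.T @ s) / n
    try:
        J_inv_half = np.linalg.cholesky(np.linalg.inv(J))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(J)
        w = np.clip(w, 1e-12, None)
        J_inv_half = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    W = np.cumsum(s @ J_inv_half, axis=0) / np.sqrt(n)

    # candidate boundaries: last index of each tied group, inside the window
    boundaries = np.flatnonzero(zs[:-1] != zs[1:])  # split after index j
    counts_left = boundaries + 1
    ok = (counts_left >= min_node_size) & (n - counts_left >= min_node_size)
    boundaries = boundaries[ok]
    if boundaries.size == 0:
        return 0.0, 1.0
    fracs = (boundaries + 1) / n
    lm = (W[boundaries] ** 2).sum(axis=1) / (fracs * (1.0 - fracs))
    stat = float(lm.max())
    if n_paths <= 0:  # statistic only (unpruned growth)
        return stat, float("nan")
    null = _suplm_null_distribution(k, fracs, n_paths, seed)
    p = float((null >= stat).mean())
    return stat, p


def cat_instability_test(scores: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Chi-square instability test for a categorical partitioning variable.

    Within-category sums of standardized scores yield a statistic that is
    asymptotically chi-square with k(C-1) degrees of freedom under
    parameter stability.  Categories with zero rows are dropped with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    z = np.asarray(z)
    n, k = scores.shape
    cats, counts = np.unique(z, return_counts=True)
    keep = counts > 0
    if (~keep).any():  # pragma: no cover - unique() never returns empties
        warnings.warn("dropping empty categories")
        cats, counts = cats[keep], counts[keep]
    C = len(cats)
    if C < 2:
        warnings.warn("constant partitioning variable; no instability testable")
        return 0.0, 1.0
    J = (scores.T @ scores) / n
    try:
        J_inv = np.linalg.inv(J)
    except np.linalg.LinAlgError:
        J_inv = np.linalg.pinv(J)
    stat = 0.0
    for c, nc in zip(cats, counts):
        sc = scores[z == c].sum(axis=0) / np.sqrt(n)
        stat += float(sc @ J_inv @ sc) / (nc / n)
    df = k * (C - 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def select_split_variable(
    pvals: dict[str, float], control: MOBControl
) -> tuple[str | None, dict[str, float]]:
    """Bonferroni pre-pruning rule: adjust each p by the number of tested
    variables (capped at 1), return the minimizing variable if its adjusted
    p is below alpha, else None.  Ties break by declared order (logged)."""
    if not pvals:
        raise ConfigurationError("pvals must be non-empty")
    k = len(pvals)
    factor = k if control.bonferroni else 1
    adjusted = {v: min(1.0, p * factor) for v, p in pvals.items()}
    best = min(adjusted, key=lambda v: adjusted[v])
    ties = [v for v, p in adjusted.items() if p == adjusted[best]]
    if len(ties) > 1:
        logger.info("instability tie between %s broken by declared order -> %s",
                    ties, ties[0])
        best = ties[0]
    if adjusted[best] < control.alpha:
        return best, adjusted
    return None, adjusted


def _is_ordered(table: pd.DataFrame, variable: str) -> bool:
    return pd.api.types.is_numeric_dtype(table[variable])


def _sse_two_arm(y: np.ndarray, treat: np.ndarray) -> float:
    sse = 0.0
    for a in (0.0, 1.0):
        sel = treat == a
        if sel.any():
            v = y[sel]
            sse += float(((v - v.mean()) ** 2).sum())
    return sse


def search_cutpoint(
    table: pd.DataFrame,
    variable: str,
    control: MOBControl,
    outcome: str = "phq9_post",
):
    """Exhaustive objective-minimizing split of a selected variable.

    Ordered variables: scan midpoint boundaries between consecutive
    distinct values, minimizing the summed child SSE of the two-arm node
    model subject to both children holding at least ``min_node_size``
    observations; the reported cutpoint is the largest value in the left
    child (splits read "<= c").  Categorical variables: exhaustive binary
    partitions up to 10 categories (beyond that, categories are ordered by
    node mean outcome and scanned as ordered; logged); returns the frozenset
    of left-child categories.  Returns None when no admissible split exists.
    """
    y = table[outcome].to_numpy(dtype=float)
    treat = (table["arm"].astype(str) == "intervention").to_numpy(dtype=float)
    n = len(y)
    if _is_ordered(table, variable):
        x = table[variable].to_numpy(dtype=float)
        order = np.argsort(x, kind="stable")
        xs, ys, ts = x[order], y[order], treat[order]
        boundaries = np.flatnonzero(xs[:-1] != xs[1:])
        nl = boundaries + 1
        ok = (nl >= control.min_node_size) & (n - nl >= control.min_node_size)
        boundaries, nl = boundaries[ok], nl[ok]
        if boundaries.size == 0:
            return None
        # per-arm prefix sums give every candidate's child SSEs in O(n)
        sse = np.zeros(len(boundaries))
        for a in (0.0, 1.0):
            ind = (ts == a).astype(float)
            cnt = np.concatenate([[0.0], np.cumsum(ind)])
            s1 = np.concatenate([[0.0], np.cumsum(ys * ind)])
            s2 = np.concatenate([[0.0], np.cumsum(ys * ys * ind)])
            cl, sl, ql = cnt[nl], s1[nl], s2[nl]
            cr, sr, qr = cnt[-1] - cl, s1[-1] - sl, s2[-1] - ql
            with np.errstate(divide="ignore", invalid="ignore"):
                sse += np.where(cl > 0, ql - sl**2 / np.where(cl > 0, cl, 1), 0.0)
                sse += np.where(cr > 0, qr - sr**2 / np.where(cr > 0, cr, 1), 0.0)
        j = int(np.argmin(sse))
        return float(xs[boundaries[j]])
    # categorical
    cats = list(pd.unique(table[variable].astype(str)))
    xcat = table[variable].astype(str).to_numpy()
    if len(cats) > 10:
        logger.info("%s has >10 categories; ordered by node mean outcome", variable)
        means = {c: y[xcat == c].mean() for c in cats}
        cats_sorted = sorted(cats, key=lambda c: means[c])
        code = np.array([cats_sorted.index(c) for c in xcat], dtype=float)
        tmp = table.copy()
        tmp["__code__"] = code
        cut = search_cutpoint(tmp, "__code__", control, outcome)
        if cut is None:
            return None
        return frozenset(cats_sorted[: int(cut) + 1])
    best, best_sse = None, np.inf
    for mask_bits in range(1, 2 ** (len(cats) - 1)):
        left = frozenset(c for i, c in enumerate(cats) if (mask_bits >> i) & 1)
        sel = np.isin(xcat, list(left))
        nl = int(sel.sum())
        if nl < control.min_node_size or n - nl < control.min_node_size:
            continue
        sse = _sse_two_arm(y[sel], treat[sel]) + _sse_two_arm(y[~sel], treat[~sel])
        if sse < best_sse - 1e-12:
            best_sse, best = sse, left
    return best


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class MOBNode:
    """One node of a fitted tree (internal or terminal)."""

    node_id: int
    n: int
    depth: int
    # internal
    split_variable: str | None = None
    cutpoint: float | None = None
    left_categories: frozenset | None = None
    right_categories: frozenset | None = None
    statistic: float | None = None
    p_adjusted: float | None = None
    left: "MOBNode | None" = None
    right: "MOBNode | None" = None
    # terminal
    model: NodeModel | None = None
    percent_of_sample: float | None = None
    effect: EffectSize | None = None
    improvement: dict | None = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None

    def route(self, row: pd.Series, lenient: bool = False) -> "MOBNode":
        node = self
        while not node.is_terminal:
            v = row[node.split_variable]
            if pd.isna(v):
                if not lenient:
                    raise ConfigurationError(
                        f"missing split variable {node.split_variable!r}; "
                        "use lenient mode for surrogate routing"
                    )
                node = node.left if node.left.n >= node.right.n else node.right
                continue
            if node.left_categories is not None:
                sv = str(v)
                known = node.left_categories | (node.right_categories or frozenset())
                if sv not in known:
                    raise ConfigurationError(
                        f"unknown category {sv!r} at split on "
                        f"{node.split_variable!r} (row {row.name})"
                    )
                node = node.left if sv in node.left_categories else node.right
            else:
                node = node.left if float(v) <= node.cutpoint else node.right
        return node


@dataclass
class MOBTree:
    """A fitted model-based recursive partition."""

    root: MOBNode
    control: MOBControl
    partitioning_vars: list[str]
    n_train: int
    fingerprint: int
    sd_standardizer: float
    converged: bool = True
    n_cycles: int = 1

    def terminal_nodes(self) -> Iterator[MOBNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_terminal:
                yield node
            else:
                stack.extend([node.right, node.left])

    @property
    def n_terminal(self) -> int:
        return sum(1 for _ in self.terminal_nodes())

    @property
    def depth(self) -> int:
        def _d(node):
            if node.is_terminal:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)


def _table_fingerprint(table: pd.DataFrame) -> int:
    return int(pd.util.hash_pandas_object(
        table.reset_index(drop=True), index=False
    ).sum() % (2**63))


def _grow(
    table: pd.DataFrame,
    outcome: str,
    partitioning_vars: Sequence[str],
    control: MOBControl,
    depth: int,
    counter: list[int],
) -> MOBNode:
    counter[0] += 1
    node = MOBNode(node_id=counter[0], n=len(table), depth=depth)
    model = fit_node_model(table, outcome)
    node.model = model
    if control.max_depth is not None and depth >= control.max_depth:
        return node
    if len(table) < 2 * control.min_node_size:
        return node
    # both arms must be present for the score matrix to be full rank
    treat = (table["arm"].astype(str) == "intervention").to_numpy()
    if treat.all() or not treat.any():
        return node
    scores = node_scores(model, table, outcome)
    unpruned = control.alpha >= 1.0
    pvals: dict[str, float] = {}
    statvals: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for v in partitioning_vars:
            if _is_ordered(table, v):
                s, p = suplm_test(
                    scores,
                    table[v].to_numpy(dtype=float),
                    min_node_size=control.min_node_size,
                    n_paths=0 if unpruned else control.n_null_paths,
                    seed=control.null_seed,
                )
            else:
                s, p = cat_instability_test(scores, table[v].astype(str).to_numpy())
            pvals[v] = p
            statvals[v] = s
    if unpruned:
        chosen = max(statvals, key=lambda v: statvals[v])
        if statvals[chosen] <= 0:
            return node
        adjusted = {v: float("nan") for v in statvals}
    else:
        chosen, adjusted = select_split_variable(pvals, control)
    if chosen is None:
        return node
    cut = search_cutpoint(table, chosen, control, outcome)
    if cut is None:
        return node
    node.split_variable = chosen
    node.p_adjusted = adjusted[chosen]
    node.statistic = statvals[chosen]
    if isinstance(cut, frozenset):
        node.left_categories = cut
        sel = table[chosen].astype(str).isin(cut).to_numpy()
        node.right_categories = frozenset(
            c for c in table[chosen].astype(str).unique() if c not in cut
        )
    else:
        node.cutpoint = float(cut)
        sel = table[chosen].to_numpy(dtype=float) <= cut
    node.left = _grow(table.loc[sel], outcome, partitioning_vars, control,
                      depth + 1, counter)
    node.right = _grow(table.loc[~sel], outcome, partitioning_vars, control,
                       depth + 1, counter)
    node.model = None
    return node


def _assignments_fast(root: MOBNode, table: pd.DataFrame) -> np.ndarray:
    """Vectorized node routing."""
    out = np.zeros(len(table), dtype=int)

    def rec(node: MOBNode, mask: np.ndarray):
        if node.is_terminal:
            out[mask] = node.node_id
            return
        if node.left_categories is not None:
            vals = table[node.split_variable].astype(str).to_numpy()[mask]
            known = node.left_categories | (node.right_categories or frozenset())
            unknown = ~np.isin(vals, list(known))
            if unknown.any():
                bad = vals[unknown][0]
                raise ConfigurationError(
                    f"unknown category {bad!r} at split on {node.split_variable!r}"
                )
            left = np.isin(vals, list(node.left_categories))
        else:
            vals = table[node.split_variable].to_numpy(dtype=float)[mask]
            left = vals <= node.cutpoint
        idx = np.flatnonzero(mask)
        lm = np.zeros(len(table), dtype=bool)
        rm = np.zeros(len(table), dtype=bool)
        lm[idx[left]] = True
        rm[idx[~left]] = True
        rec(node.left, lm)
        rec(node.right, rm)

    rec(root, np.ones(len(table), dtype=bool))
    return out


def grow_mob_tree(
    table: pd.DataFrame,
    partitioning_vars: Sequence[str],
    control: MOBControl | None = None,
    outcome: str = "phq9_post",
    rci_config: RCIConfig | None = None,
) -> MOBTree:
    """Grow the full tree on a complete table.

    With ``mixed_effects`` on, alternates between (a) estimating trial
    random effects globally given the current tree-implied fixed structure
    and (b) re-growing the tree on the outcome minus the predicted
    random-effect contribution, until node assignments stabilize (at most
    ``max_cycles``; a non-converged alternation returns the last tree with
    a warning flag).  Terminal nodes carry the node-model coefficients, the
    conditional effect size d_i (treatment coefficient standardized by the
    pooled baseline SD of the training sample) and per-arm reliable-
    improvement rates.
    """
    control = control or MOBControl()
    control.validate()
    if not partitioning_vars:
        raise ConfigurationError("partitioning_vars must be non-empty")
    work_cols = set([outcome, "arm"]) | set(partitioning_vars)
    if control.mixed_effects:
        work_cols |= {"trial", "phq9_baseline"}
    if table[list(work_cols)].isna().any().any():
        raise ConfigurationError(
            "tree growth requires complete data; aggregate the imputed stack first"
        )
    table = table.reset_index(drop=True)
    y_raw = table[outcome].to_numpy(dtype=float)
    if "phq9_baseline" in table.columns:
        sd_std = pooled_baseline_sd(table)
    else:  # degenerate working tables without a baseline column
        sd_std = float(np.std(y_raw, ddof=1))
    # growth operates on a slim working table: recursive node slicing only
    # pays for the columns it actually uses
    work = table[sorted(work_cols)].copy()
    adj_col = "__y_adj__"
    work[adj_col] = y_raw
    converged = True
    n_cycles = 1
    if control.mixed_effects:
        # Alternation: (a) global model with the tree-implied fixed structure
        # (per-node intercept and treatment effect), trial-stratified baseline
        # adjustment and trial random effects; (b) re-grow the tree on the
        # outcome minus the baseline and random-effect contributions.  The
        # baseline effect is removed globally so instability tests in the
        # nodes respond to effect modification, not to prognostic gradients.
        treat = (table["arm"].astype(str) == "intervention").to_numpy(dtype=float)
        base = table["phq9_baseline"].to_numpy(dtype=float)
        groups = table["trial"].astype(str).to_numpy()
        glevels = sorted(set(groups))
        multi_trial = len(glevels) >= 2
        Z = np.column_stack([np.ones(len(table)), treat])
        assign = np.zeros(len(table), dtype=int)
        seen: dict[bytes, int] = {}
        root = None
        for cycle in range(control.max_cycles):
            n_cycles = cycle + 1
            node_ids = np.unique(assign)
            X_cols, names = [], []
            for nid in node_ids:
                ind = (assign == nid).astype(float)
                X_cols += [ind, ind * treat]
                names += [f"node{nid}", f"node{nid}:treatment"]
            for lv in glevels:
                gmask = (groups == lv).astype(float)
                X_cols.append(gmask * base)
                names.append(f"trial[{lv}]:phq9_baseline")
            X = np.column_stack(X_cols)
            n_base = len(glevels)
            if multi_trial:
                fit = mpl_lmm_arrays(y_raw, X, names, Z, groups, control.prior)
                r = y_raw - X @ fit.beta
                G_inv = np.linalg.inv(fit.ranef_cov)
                ranef_contrib = np.zeros(len(table))
                for lv in glevels:
                    i = np.flatnonzero(groups == lv)
                    Zg = Z[i]
                    M = fit.sigma2 * G_inv + Zg.T @ Zg
                    u = np.linalg.solve(M, Zg.T @ r[i])
                    ranef_contrib[i] = Zg @ u
                beta = fit.beta
            else:
                beta, *_ = np.linalg.lstsq(X, y_raw, rcond=None)
                ranef_contrib = np.zeros(len(table))
            base_contrib = X[:, -n_base:] @ beta[-n_base:]
            work[adj_col] = y_raw - base_contrib - ranef_contrib
            counter = [0]
            root = _grow(work, adj_col, partitioning_vars, control, 0, counter)
            new_assign = _assignments_fast(root, table)
            if np.array_equal(new_assign, assign):
                break
            key = new_assign.tobytes()
            if key in seen:
                # assignments revisit an earlier state: the alternation cycles
                # between equally supported partitions; keep the current tree
                logger.info("alternation cycled after %d cycles; stopping", n_cycles)
                break
            seen[key] = cycle
            assign = new_assign
        else:
            converged = False
            warnings.warn("tree/random-effects alternation did not converge; "
                          "returning the last tree")
    else:
        counter = [0]
        root = _grow(work, adj_col, partitioning_vars, control, 0, counter)

    tree = MOBTree(
        root=root,
        control=control,
        partitioning_vars=list(partitioning_vars),
        n_train=len(table),
        fingerprint=_table_fingerprint(table),
        sd_standardizer=sd_std,
        converged=converged,
        n_cycles=n_cycles,
    )
    _populate_terminal_stats(tree, table, outcome, rci_config)
    return tree


def _populate_terminal_stats(
    tree: MOBTree,
    table: pd.DataFrame,
    outcome: str,
    rci_config: RCIConfig | None,
) -> None:
    # terminal summaries are computed on the raw outcome: the global
    # baseline/random-effect adjustment steers split selection only, so the
    # reported node models are plain two-arm means of the node's subset
    from .effects import reliable_change

    assign = _assignments_fast(tree.root, table)
    rci = rci_config or RCIConfig()
    if rci.sd_baseline is None:
        # one global reliable-change threshold for every node: the index is a
        # property of the instrument and the training sample, not the subgroup
        rci = replace(rci, sd_baseline=tree.sd_standardizer)
    for node in tree.terminal_nodes():
        sel = assign == node.node_id
        sub = table.loc[sel].copy()
        model = fit_node_model(sub, outcome)
        node.model = model
        node.n = int(sel.sum())
        node.percent_of_sample = 100.0 * node.n / tree.n_train
        se_t = float(np.sqrt(model.cov_beta[1, 1]))
        b = float(model.beta[1])
        node.effect = cohens_d(b, (b - 1.96 * se_t, b + 1.96 * se_t),
                               tree.sd_standardizer)
        both_arms = sub["arm"].nunique() == 2
        has_rci_cols = {"phq9_baseline", "phq9_post"} <= set(sub.columns)
        if both_arms and has_rci_cols and not sub["phq9_post"].isna().any():
            rc = reliable_change(sub, rci)
            node.improvement = dict(
                n_improved=rc.n_improved,
                n_total=rc.n_total,
                rate_percent=rc.rate_percent,
                p=rc.comparison.p,
            )


def predict_tree(
    tree: MOBTree,
    newdata: pd.DataFrame,
    lenient: bool = False,
) -> pd.DataFrame:
    """Route rows through the split rules and evaluate the terminal models.

    Returns a frame with the terminal node id and the node-model prediction
    at each row's treatment indicator.  A missing split variable raises in
    strict mode; in lenient mode the row follows the larger child (logged).
    Boundary values (exactly at a "<= c" cutpoint) go left.
    """
    needed = set(v for v in tree.partitioning_vars)
    missing_cols = [c for c in needed | {"arm"} if c not in newdata.columns]
    if missing_cols:
        raise ConfigurationError(f"newdata lacks columns: {missing_cols}")
    node_ids = np.empty(len(newdata), dtype=int)
    preds = np.empty(len(newdata))
    treat = (newdata["arm"].astype(str) == "intervention").to_numpy(dtype=float)
    has_na = newdata[list(needed)].isna().any().any()
    if not has_na:
        node_ids = _assignments_fast(tree.root, newdata.reset_index(drop=True))
        models = {n.node_id: n.model for n in tree.terminal_nodes()}
        for nid in np.unique(node_ids):
            m = models[nid]
            sel = node_ids == nid
            preds[sel] = m.beta[0] + m.beta[1] * treat[sel]
    else:
        if not lenient:
            raise ConfigurationError(
                "newdata has missing split variables; use lenient=True"
            )
        logger.info("lenient routing: missing split values follow the larger child")
        for pos, (_, row) in enumerate(newdata.iterrows()):
            node = tree.root.route(row, lenient=True)
            node_ids[pos] = node.node_id
            preds[pos] = node.model.beta[0] + node.model.beta[1] * treat[pos]
    return pd.DataFrame({"node": node_ids, "prediction": preds},
                        index=newdata.index)
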