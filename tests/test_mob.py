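"""MOB machinery: scores, instability tests, splitting, growth, prediction."""

import numpy as np
import pandas as pd
import pytest

from hetmob.exceptions import ConfigurationError
from hetmob.mob import (
    MOBControl,
    cat_instability_test,
    fit_node_model,
    grow_mob_tree,
    node_scores,
    predict_tree,
    search_cutpoint,
    select_split_variable,
    suplm_pvalue_crossing,
    suplm_test,
)
from hetmob.synthetic import (
    SubgroupRule,
    SyntheticConfig,
    generate_trial_pair,
    uniform_effect_rules,
)


def _toy_node(n=60, seed=0, effect=0.5):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(
        {
            "arm": rng.choice(["control", "intervention"], n),
            "z": rng.normal(size=n),
        }
    )
    t["phq9_post"] = 1.0 + effect * (t["arm"] == "intervention") + rng.normal(
        0, 1.0, n
    )
    return t


class TestNodeScores:
    def test_column_sums_vanish(self):
        t = _toy_node()
        fit = fit_node_model(t)
        s = node_scores(fit, t)
        assert np.abs(s.sum(axis=0)).max() < 1e-8 * len(t)

    def test_matches_finite_difference_gradient(self):
        t = _toy_node(n=5, seed=1)
        fit = fit_node_model(t)
        s = node_scores(fit, t)
        X = np.column_stack(
            [np.ones(5), (t["arm"] == "intervention").to_numpy(float)]
        )
        y = t["phq9_post"].to_numpy()

        def loglik_row(beta, i):
            resid = y[i] - X[i] @ beta
            return -0.5 * np.log(2 * np.pi * fit.sigma2) - resid**2 / (
                2 * fit.sigma2
            )

        eps = 1e-6
        for i in range(5):
            for j in range(2):
                bp, bm = fit.beta.copy(), fit.beta.copy()
                bp[j] += eps
                bm[j] -= eps
                num = (loglik_row(bp, i) - loglik_row(bm, i)) / (2 * eps)
                assert s[i, j] == pytest.approx(num, abs=1e-5)

    def test_zero_residual_zero_score(self):
        t = _toy_node(n=20, seed=2)
        fit = fit_node_model(t)
        y = t["phq9_post"].to_numpy()
        X = np.column_stack(
            [np.ones(20), (t["arm"] == "intervention").to_numpy(float)]
        )
        resid = y - X @ fit.beta
        i = int(np.argmin(np.abs(resid)))
        t.loc[i, "phq9_post"] = float(X[i] @ fit.beta)  # force exact fit
        fit2 = fit_node_model(t)
        s = node_scores(fit2, t)
        resid2 = t["phq9_post"].to_numpy() - X @ fit2.beta
        j = int(np.argmin(np.abs(resid2)))
        assert np.abs(s[j]).max() < 1e-6 or np.abs(resid2[j]) > 1e-10


class TestSupLM:
    def test_zero_scores_give_null_result(self):
        with pytest.warns(UserWarning):
            stat, p = suplm_test(np.zeros((50, 2)), np.full(50, 1.0))
        assert (stat, p) == (0.0, 1.0)

    def test_power_against_planted_shift(self):
        # 1-SD parameter shift at the median of z: tiny p-values throughout
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            t = pd.DataFrame(
                {
                    "arm": rng.choice(["control", "intervention"], n),
                    "z": rng.normal(size=n),
                }
            )
            shift = (t["z"] > np.median(t["z"])).to_numpy(float)
            t["phq9_post"] = shift + rng.normal(0, 1.0, n)
            fit = fit_node_model(t)
            s = node_scores(fit, t)
            _, p = suplm_test(s, t["z"].to_numpy())
            hits += p < 1e-4
        assert hits >= 19

    def test_crossing_approximation_tracks_simulation(self):
        rng = np.random.default_rng(3)
        n = 400
        t = pd.DataFrame({"arm": ["control"] * n})
        y = rng.normal(size=n)
        scores = (y - y.mean())[:, None] / y.var()
        z = rng.normal(size=n)
        stat, p_sim = suplm_test(scores, z, min_node_size=40)
        a, b = 40 / n, 1 - 40 / n
        p_approx = suplm_pvalue_crossing(stat, a, b)
        assert p_approx == pytest.approx(p_sim, abs=0.08)


class TestCatInstability:
    def test_zero_scores(self):
        stat, p = cat_instability_test(np.zeros((40, 2)),
                                       np.array(["a", "b"] * 20))
        assert (stat, p) == (0.0, 1.0)

    def test_hand_computed_quadratic_form(self):
        # 4 rows, two balanced categories, k=1 scores
        s = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        z = np.array(["a", "a", "b", "b"])
        stat, p = cat_instability_test(s, z)
        n = 4
        J = float((s * s).mean())
        expected = 0.0
        for c in ("a", "b"):
            sc = s[z == c].sum() / np.sqrt(n)
            expected += (sc**2 / J) / (2 / 4)
        assert stat == pytest.approx(expected)
        from scipy import stats as st

        assert p == pytest.approx(st.chi2.sf(expected, 1))


class TestSelectSplitVariable:
    def test_no_significance(self):
        ctrl = MOBControl()
        var, adj = select_split_variable({"a": 0.30, "b": 0.20}, ctrl)
        assert var is None
        assert adj == {"a": 0.60, "b": 0.40}

    def test_clear_winner(self):
        var, adj = select_split_variable({"a": 0.001, "b": 0.20}, MOBControl())
        assert var == "a"
        assert adj["a"] == pytest.approx(0.002)

    def test_tie_break_by_declared_order(self):
        var, _ = select_split_variable({"a": 0.01, "b": 0.01}, MOBControl())
        assert var == "a"

    def test_bonferroni_off(self):
        ctrl = MOBControl(bonferroni=False)
        var, adj = select_split_variable({"a": 0.04, "b": 0.50}, ctrl)
        assert var == "a"
        assert adj["a"] == 0.04


class TestSearchCutpoint:
    def test_planted_step_recovered(self):
        rng = np.random.default_rng(7)
        n = 400
        t = pd.DataFrame(
            {
                "arm": rng.choice(["control", "intervention"], n),
                "x": rng.integers(0, 21, n).astype(float),
            }
        )
        effect = np.where(t["x"] <= 10, -1.0, -8.0)
        t["phq9_post"] = effect * (t["arm"] == "intervention") + rng.normal(
            0, 0.5, n
        )
        cut = search_cutpoint(t, "x", MOBControl(mixed_effects=False))
        assert cut == 10.0

    def test_binary_single_candidate(self):
        rng = np.random.default_rng(8)
        n = 100
        t = pd.DataFrame(
            {
                "arm": rng.choice(["control", "intervention"], n),
                "flag": rng.choice(["yes", "no"], n),
            }
        )
        t["phq9_post"] = rng.normal(size=n)
        cut = search_cutpoint(t, "flag", MOBControl(min_node_size=20))
        assert isinstance(cut, frozenset)
        assert cut in (frozenset({"yes"}), frozenset({"no"}))

    def test_min_node_size_binding(self):
        t = _toy_node(n=30)
        t["x"] = np.arange(30, dtype=float)
        assert search_cutpoint(t, "x", MOBControl(min_node_size=20)) is None


class TestGrowAndPredict:
    @pytest.fixture(scope="class")
    def planted_tree(self):
        rules = [
            SubgroupRule("lo", lambda t: t["phq9_baseline"].to_numpy() <= 10, 0.0),
            SubgroupRule(
                "mid",
                lambda t: (t["phq9_baseline"].to_numpy() > 10)
                & (t["pseq"].to_numpy() <= 38),
                -1.31,
            ),
            SubgroupRule(
                "hi",
                lambda t: (t["phq9_baseline"].to_numpy() > 10)
                & (t["pseq"].to_numpy() > 38),
                0.24,
            ),
        ]
        cfg = SyntheticConfig(seed=42, true_subgroup_rules=rules)
        table = generate_trial_pair(cfg)
        tree = grow_mob_tree(table, ["phq9_baseline", "pseq", "age"])
        return table, tree

    def test_terminal_invariants(self, planted_tree):
        table, tree = planted_tree
        terms = list(tree.terminal_nodes())
        assert sum(n.n for n in terms) == len(table)
        assert all(n.n >= tree.control.min_node_size for n in terms)
        assert sum(n.percent_of_sample for n in terms) == pytest.approx(100.0)

    def test_training_assignment_consistency(self, planted_tree):
        table, tree = planted_tree
        pred = predict_tree(tree, table)
        from hetmob.mob import _assignments_fast

        assert (pred["node"].to_numpy()
                == _assignments_fast(tree.root, table)).all()

    def test_row_permutation_invariance(self, planted_tree):
        table, tree = planted_tree
        rng = np.random.default_rng(0)
        perm = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
        tree2 = grow_mob_tree(perm, ["phq9_baseline", "pseq", "age"])

        def shape(node):
            if node.is_terminal:
                return ("leaf", node.n)
            return (node.split_variable, node.cutpoint,
                    shape(node.left), shape(node.right))

        assert shape(tree.root) == shape(tree2.root)

    def test_boundary_routed_left(self, planted_tree):
        table, tree = planted_tree
        node = tree.root
        assert not node.is_terminal
        row = table.iloc[[0]].copy()
        row[node.split_variable] = node.cutpoint  # exactly at the cutpoint
        out = predict_tree(tree, row)
        left_ids = set()

        def collect(nd):
            if nd.is_terminal:
                left_ids.add(nd.node_id)
            else:
                collect(nd.left)
                collect(nd.right)

        collect(node.left)
        assert out["node"].iloc[0] in left_ids

    def test_single_node_tree_two_arm_means(self):
        cfg = SyntheticConfig(seed=9, true_subgroup_rules=uniform_effect_rules(0.0),
                              tau2_slope=0.0, tau2_intercept=0.0)
        t = generate_trial_pair(cfg)
        tree = grow_mob_tree(t, ["age"])  # no heterogeneity to find
        if tree.n_terminal == 1:
            pred = predict_tree(tree, t)["prediction"]
            for arm in ("control", "intervention"):
                sel = (t["arm"] == arm).to_numpy()
                assert np.allclose(pred[sel], t.loc[sel, "phq9_post"].mean(),
                                   atol=1e-8)

    def test_unknown_category_rejected(self):
        rng = np.random.default_rng(10)
        n = 300
        t = pd.DataFrame(
            {
                "trial": np.repeat(["trial_A", "trial_B"], n // 2),
                "arm": rng.choice(["control", "intervention"], n),
                "phq9_baseline": rng.integers(5, 25, n).astype(float),
                "flag": rng.choice(["yes", "no"], n),
            }
        )
        t["phq9_post"] = (
            5.0
            + np.where(t["flag"] == "yes", -4.0, 0.0)
            * (t["arm"] == "intervention")
            + rng.normal(0, 1, n)
        )
        tree = grow_mob_tree(t, ["flag"],
                             MOBControl(mixed_effects=False, min_node_size=20))
        if tree.n_terminal > 1:
            bad = t.iloc[[0]].copy()
            bad["flag"] = "maybe"
            with pytest.raises(ConfigurationError, match="maybe"):
                predict_tree(tree, bad)

    def test_missing_split_variable_strict_and_lenient(self, planted_tree):
        table, tree = planted_tree
        row = table.iloc[[0]].copy()
        row[tree.root.split_variable] = np.nan
        with pytest.raises(ConfigurationError, match="lenient"):
            predict_tree(tree, row)
        out = predict_tree(tree, row, lenient=True)
        assert len(out) == 1

    def test_incomplete_data_rejected(self, planted_tree):
        table, _ = planted_tree
        t = table.copy()
        t.loc[0, "phq9_post"] = np.nan
        with pytest.raises(ConfigurationError, match="complete"):
            grow_mob_tree(t, ["phq9_baseline"])

    def test_first_split_matches_brute_force_oracle(self):
        # mixed effects off, one candidate variable: the first split equals
        # an exhaustive search minimizing total child SSE
        rng = np.random.default_rng(11)
        n = 300
        t = pd.DataFrame(
            {
                "trial": "t1",
                "arm": rng.choice(["control", "intervention"], n),
                "x": rng.integers(0, 25, n).astype(float),
            }
        )
        t["phq9_post"] = (
            np.where(t["x"] <= 13, 0.0, -5.0) * (t["arm"] == "intervention")
            + rng.normal(0, 1.0, n)
        )
        ctrl = MOBControl(mixed_effects=False, min_node_size=20, max_depth=1)
        tree = grow_mob_tree(t, ["x"], ctrl)
        assert not tree.root.is_terminal
        y = t["phq9_post"].to_numpy()
        tr = (t["arm"] == "intervention").to_numpy(float)
        x = t["x"].to_numpy()

        def sse_two(yv, tv):
            out = 0.0
            for a in (0.0, 1.0):
                sel = tv == a
                if sel.any():
                    out += float(((yv[sel] - yv[sel].mean()) ** 2).sum())
            return out

        best, best_sse = None, np.inf
        for c in np.unique(x)[:-1]:
            sel = x <= c
            if sel.sum() < 20 or (~sel).sum() < 20:
                continue
            s = sse_two(y[sel], tr[sel]) + sse_two(y[~sel], tr[~sel])
            if s < best_sse - 1e-12:
                best_sse, best = s, float(c)
        assert tree.root.cutpoint == best
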