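"""Average treatment effect, Cohen's d, reliable change, moderation."""

import numpy as np
import pandas as pd
import pytest

from conftest import wrap_stack
from hetmob.effects import (
    RCIConfig,
    cohens_d,
    estimate_ate,
    percentile_change_analysis,
    reliable_change,
    univariate_moderation,
)
from hetmob.exceptions import ConfigurationError
from hetmob.synthetic import (
    SubgroupRule,
    SyntheticConfig,
    generate_trial_pair,
    uniform_effect_rules,
)


class TestCohensD:
    def test_null_effect(self):
        e = cohens_d(0.0, (-1.0, 1.0), 5.0)
        assert e.d == 0.0

    def test_direct_ratio(self):
        e = cohens_d(-2.165, (-3.0, -1.0), 5.0)
        assert e.d == pytest.approx(-0.433)
        assert (e.ci_low, e.ci_high) == (pytest.approx(-0.6), pytest.approx(-0.2))

    def test_invalid_sd(self):
        with pytest.raises(ConfigurationError):
            cohens_d(1.0, (0.0, 2.0), 0.0)


class TestEstimateATE:
    def test_location_invariance(self, default_table):
        pooled, _ = estimate_ate(wrap_stack(default_table))
        shifted = default_table.copy()
        shifted["phq9_post"] = shifted["phq9_post"] + 3.0
        pooled2, _ = estimate_ate(wrap_stack(shifted))
        assert pooled2.estimate == pytest.approx(pooled.estimate, abs=1e-4)

    def test_null_coverage(self):
        # CI covers zero at roughly the nominal rate under the null
        hits, ds = 0, []
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=seed, n_per_trial=(80, 80),
                                  true_subgroup_rules=uniform_effect_rules(0.0),
                                  tau2_slope=0.0)
            stack = wrap_stack(generate_trial_pair(cfg))
            pooled, effect = estimate_ate(stack)
            ds.append(effect.d)
            hits += pooled.ci_low <= 0.0 <= pooled.ci_high
        assert abs(np.mean(ds)) < 3 * np.std(ds) / np.sqrt(n_seeds)
        assert hits / n_seeds > 0.85


class TestReliableChange:
    def test_no_change_no_improvement(self, default_table):
        t = default_table.copy()
        t["phq9_post"] = t["phq9_baseline"]
        rc = reliable_change(t, RCIConfig())
        assert rc.n_improved == {"control": 0, "intervention": 0}

    def test_jacobson_truax_threshold(self):
        cfg = RCIConfig(reliability=0.84, sd_baseline=4.55)
        base = pd.DataFrame(
            {
                "trial": "t",
                "arm": ["control", "intervention"] * 2,
                "phq9_baseline": [15.0, 15.0, 15.0, 15.0],
                "phq9_post": [9.0, 9.0, 10.0, 10.0],  # changes -6 and -5
            }
        )
        rc = reliable_change(base, cfg)
        assert rc.se_diff == pytest.approx(4.55 * np.sqrt(0.32), abs=1e-3)
        assert rc.threshold == pytest.approx(5.045, abs=1e-3)
        cls = rc.classification()
        assert list(cls) == [True, True, False, False]

    def test_shift_invariance(self, default_table):
        cfg = RCIConfig(sd_baseline=4.55)
        rc1 = reliable_change(default_table, cfg)
        t = default_table.copy()
        t["phq9_baseline"] += 2
        t["phq9_post"] += 2
        rc2 = reliable_change(t, cfg)
        assert rc1.n_improved == rc2.n_improved

    def test_reported_integer_rates(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {
                "trial": "t",
                "arm": ["intervention"] * 253 + ["control"] * 251,
                "phq9_baseline": 15.0,
                "phq9_post": 15.0,
            }
        )
        # plant exactly 62 and 28 reliable improvements
        t.iloc[:62, t.columns.get_loc("phq9_post")] = 5.0
        t.iloc[253:281, t.columns.get_loc("phq9_post")] = 5.0
        rc = reliable_change(t, RCIConfig(sd_baseline=4.55))
        assert rc.n_improved == {"control": 28, "intervention": 62}
        assert rc.rate_percent == {"control": 11, "intervention": 25}


class TestUnivariateModeration:
    def test_constant_moderator_rejected(self, default_table):
        t = default_table.copy()
        t["gender"] = "female"
        with pytest.raises(ConfigurationError, match="constant"):
            univariate_moderation(wrap_stack(t), "gender")

    @pytest.mark.parametrize("engine", ["mpl_lmm", "ols_cr2"])
    def test_binary_interaction_recovery(self, engine):
        # planted -1.95-point interaction on previous pain medication
        betas = []
        for seed in range(15):
            cfg = SyntheticConfig(seed=seed, tau2_slope=0.0)
            t = generate_trial_pair(cfg)
            med = (t["prev_pain_medication"] == "yes").to_numpy(float)
            treat = (t["arm"] == "intervention").to_numpy(float)
            rng = np.random.default_rng(seed)
            t["phq9_post"] = np.clip(np.round(
                4 + 0.5 * t["phq9_baseline"] - 1.0 * treat
                - 1.95 * treat * med + rng.normal(0, 4.0, len(t))
            ), 0, 27)
            res = univariate_moderation(wrap_stack(t), "prev_pain_medication",
                                        engine=engine)
            betas.append(res.beta_interaction)
        assert np.mean(betas) == pytest.approx(-1.95, abs=0.35)

    def test_binary_moderator_subgroup_effects(self, default_table):
        res = univariate_moderation(wrap_stack(default_table),
                                    "prev_pain_medication")
        assert res.subgroup_effects is not None
        assert set(res.subgroup_effects) == {"0", "1"}
        assert 0 <= res.p <= 1

    def test_engines_agree_without_heterogeneity(self):
        cfg = SyntheticConfig(seed=33, tau2_slope=0.0, tau2_intercept=0.0)
        stack = wrap_stack(generate_trial_pair(cfg))
        a = univariate_moderation(stack, "pseq", engine="mpl_lmm")
        b = univariate_moderation(stack, "pseq", engine="ols_cr2")
        assert a.beta_interaction == pytest.approx(b.beta_interaction, abs=0.1)


class TestPercentileChange:
    def test_exact_quintile_split(self):
        n = 100
        t = pd.DataFrame(
            {
                "trial": "t",
                "arm": ["control", "intervention"] * (n // 2),
                "phq9_baseline": 10.0,
                "phq9_post": 9.0,
                "pseq": np.arange(n, dtype=float),
            }
        )
        pt = percentile_change_analysis(wrap_stack(t), "pseq")
        sizes = pt.table.groupby("band")["n"].sum()
        assert (sizes == 20).all()
        assert pt.table["n"].sum() == n

    def test_hand_computed_band_means(self, tiny_table):
        pt = percentile_change_analysis(wrap_stack(tiny_table), "pseq")
        t = tiny_table
        change = t["phq9_post"] - t["phq9_baseline"]
        qs = np.quantile(t["pseq"], [0.2, 0.4, 0.6, 0.8])
        band = np.clip(np.searchsorted(qs, t["pseq"], side="left"), 0, 4)
        for b, label in enumerate(pt.bands):
            for arm in ("control", "intervention"):
                sel = (band == b) & (t["arm"] == arm).to_numpy()
                row = pt.table[(pt.table["band"] == label)
                               & (pt.table["arm"] == arm)]
                if sel.any():
                    assert row["mean_change"].iloc[0] == pytest.approx(
                        change[sel].mean()
                    )

    def test_monotone_gradient_detected(self):
        # planted effect increasing in the moderator: band arm-differences
        # are monotone in most replications
        mono = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.normal(0, 1, n)
            treat = rng.random(n) < 0.5
            t = pd.DataFrame(
                {
                    "trial": "t",
                    "arm": np.where(treat, "intervention", "control"),
                    "phq9_baseline": 10.0,
                    "pseq": x,
                }
            )
            t["phq9_post"] = 10.0 + treat * (-2.0 * x) + rng.normal(0, 1.0, n)
            pt = percentile_change_analysis(wrap_stack(t), "pseq")
            piv = pt.table.pivot(index="band", columns="arm",
                                 values="mean_change").loc[pt.bands]
            diff = (piv["intervention"] - piv["control"]).to_numpy()
            mono += (np.diff(diff) < 0).all()
        assert mono / n_seeds >= 0.9

    def test_too_few_distinct_values(self, default_table):
        t = default_table.copy()
        t["spe"] = (t["spe"] > 1).astype(float)  # two distinct values
        with pytest.raises(ConfigurationError, match="categorical"):
            percentile_change_analysis(wrap_stack(t), "spe")
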