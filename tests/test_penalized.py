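"""Penalized estimators: Wishart penalty, MPL mixed model, CR2, LASSO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetmob.exceptions import CollinearityError, ConfigurationError
from hetmob.penalized import (
    WishartPrior,
    design_matrix,
    fit_lasso_interactions,
    fit_mpl_lmm,
    fit_ols_cr2,
    wishart_log_penalty,
)
from hetmob.synthetic import SyntheticConfig, generate_trial_pair


class TestWishartPenalty:
    def test_exponent_vanishes_at_nu_q_plus_one(self):
        # nu = q + 1 kills the log-determinant term
        cov = np.array([[2.0, 0.3], [0.3, 1.5]])
        prior = WishartPrior(nu=3, scale=0.05)
        expected = -0.5 * np.trace(np.linalg.inv(0.05 * np.eye(2)) @ cov)
        assert wishart_log_penalty(cov, prior) == pytest.approx(expected)

    def test_default_prior_at_scale_matrix(self):
        # q=2, nu=4, scale=0.05 I evaluated at cov=0.05 I, against an
        # independent density implementation (scipy.stats.wishart)
        cov = 0.05 * np.eye(2)
        prior = WishartPrior(nu=4, scale=0.05)
        direct = 0.5 * (4 - 2 - 1) * np.log(np.linalg.det(cov)) - 0.5 * np.trace(
            np.linalg.inv(0.05 * np.eye(2)) @ cov
        )
        assert wishart_log_penalty(cov, prior) == pytest.approx(direct)
        # cross-check against scipy's normalized logpdf up to the constant
        ref = stats.wishart(df=4, scale=0.05 * np.eye(2))
        offset1 = ref.logpdf(cov) - wishart_log_penalty(cov, prior)
        cov2 = np.array([[0.1, 0.02], [0.02, 0.07]])
        offset2 = ref.logpdf(cov2) - wishart_log_penalty(cov2, prior)
        assert offset1 == pytest.approx(offset2)  # constant normalizer

    def test_scaling_identity(self):
        cov = np.array([[0.2, 0.05], [0.05, 0.4]])
        prior = WishartPrior(nu=4, scale=0.05)
        q = 2
        lhs = wishart_log_penalty(2 * cov, prior) - wishart_log_penalty(cov, prior)
        rhs = 0.5 * (prior.nu - q - 1) * q * np.log(2) - 0.5 * np.trace(
            np.linalg.inv(0.05 * np.eye(q)) @ cov
        )
        assert lhs == pytest.approx(rhs)

    def test_non_pd_cov_rejected(self):
        with pytest.raises(ConfigurationError):
            wishart_log_penalty(np.array([[1.0, 2.0], [2.0, 1.0]]),
                                WishartPrior())


class TestMPLMixedModel:
    def test_single_trial_flat_prior_equals_ols(self):
        rng = np.random.default_rng(0)
        n = 80
        t = pd.DataFrame(
            {
                "trial": "only",
                "arm": rng.choice(["control", "intervention"], n),
                "x": rng.normal(size=n),
            }
        )
        t["phq9_post"] = 2 + 0.5 * t["x"] + rng.normal(size=n)
        fit = fit_mpl_lmm(t, "phq9_post", ["1", "x", "treatment"], prior=None,
                          random_terms=())
        X, _ = design_matrix(t, ["1", "x", "treatment"])
        beta_ols = np.linalg.lstsq(X, t["phq9_post"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)

    def test_score_columns_sum_to_zero(self, default_table):
        fit = fit_mpl_lmm(default_table, "phq9_post",
                          ["trial", "trial:phq9_baseline", "treatment"])
        assert np.abs(fit.scores.sum(axis=0)).max() < 1e-6 * len(default_table)
        assert fit.converged
        w = np.linalg.eigvalsh(fit.ranef_cov)
        assert w.min() > 0  # prior rules out boundary fits

    def test_identical_trials_shrink_to_prior_mode(self):
        rng = np.random.default_rng(1)
        n = 60
        half = pd.DataFrame(
            {
                "arm": rng.choice(["control", "intervention"], n),
                "phq9_baseline": rng.integers(5, 20, n).astype(float),
            }
        )
        half["phq9_post"] = 3 + 0.5 * half["phq9_baseline"] + rng.normal(size=n)
        t = pd.concat(
            [half.assign(trial="trial_A"), half.assign(trial="trial_B")],
            ignore_index=True,
        )
        fit = fit_mpl_lmm(t, "phq9_post", ["1", "phq9_baseline", "treatment"])
        prior_mode = (4 - 2 - 1) * 0.05  # (nu - q - 1) * scale
        assert 0 < fit.tau2_slope <= prior_mode + 1e-3
        assert 0 < fit.tau2_intercept <= prior_mode + 1e-3

    def test_tau2_recovery_many_trials(self):
        # 50 trials of 200 with planted tau2_slope = 0.48; the median ratio of
        # the estimate to the realized deviation variance is within 20% of 1
        # (comparing to the realized variance removes the dominant
        # variance-of-variance noise of the 50 drawn deviations)
        ratios = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            frames, devs = [], []
            for g in range(50):
                slope_dev = rng.normal(0, np.sqrt(0.48))
                devs.append(slope_dev)
                arm = rng.random(200) < 0.5
                # unit residual scale so the likelihood dominates the prior
                y = 1.0 + arm * (-2.0 + slope_dev) + rng.normal(0, 1.0, 200)
                frames.append(pd.DataFrame({
                    "trial": f"t{g:02d}",
                    "arm": np.where(arm, "intervention", "control"),
                    "phq9_post": y,
                }))
            t = pd.concat(frames, ignore_index=True)
            fit = fit_mpl_lmm(t, "phq9_post", ["1", "treatment"])
            ratios.append(fit.tau2_slope / np.var(devs, ddof=1))
        assert np.median(ratios) == pytest.approx(1.0, abs=0.20)

    def test_collinear_terms_named(self, default_table):
        with pytest.raises(CollinearityError, match="treatment"):
            fit_mpl_lmm(default_table, "phq9_post",
                        ["1", "treatment", "treatment"])

    def test_missing_outcome_rejected(self, default_table):
        t = default_table.copy()
        t.loc[0, "phq9_post"] = np.nan
        with pytest.raises(ConfigurationError, match="missing"):
            fit_mpl_lmm(t, "phq9_post", ["1", "treatment"])


class TestCR2:
    @staticmethod
    def _toy(n_clusters, per, seed=0, sd=1.0):
        rng = np.random.default_rng(seed)
        n = n_clusters * per
        t = pd.DataFrame(
            {
                "trial": np.repeat([f"c{i}" for i in range(n_clusters)], per),
                "arm": rng.choice(["control", "intervention"], n),
                "x": rng.normal(size=n),
            }
        )
        t["phq9_post"] = 1 + 0.4 * t["x"] + rng.normal(0, sd, n)
        return t

    def test_perfect_fit_gives_zero_se(self):
        t = self._toy(4, 10, sd=1.0)
        t["phq9_post"] = 2.0 + 3.0 * t["x"]  # exactly linear
        fit = fit_ols_cr2(t, "phq9_post", ["1", "x"], cluster="trial")
        assert np.allclose(list(fit.fixed_se.values()), 0.0, atol=1e-8)

    def test_singleton_clusters_equal_hc2(self):
        t = self._toy(40, 1, seed=3)
        fit = fit_ols_cr2(t, "phq9_post", ["1", "x", "treatment"],
                          cluster="trial")
        import statsmodels.api as sm

        X, _ = design_matrix(t, ["1", "x", "treatment"])
        ref = sm.OLS(t["phq9_post"].to_numpy(), X).fit(cov_type="HC2")
        assert np.allclose(np.sqrt(np.diag(fit.vcov)), ref.bse, atol=1e-10)

    def test_variances_nonnegative(self, default_table):
        fit = fit_ols_cr2(default_table, "phq9_post",
                          ["trial", "phq9_baseline", "treatment"])
        assert (np.diag(fit.vcov) >= 0).all()

    def test_too_small_cluster_instructive_error(self):
        t = self._toy(2, 2)
        t = pd.concat([t, t.iloc[:1].assign(trial="solo")], ignore_index=True)
        with pytest.raises(ConfigurationError, match="drop|merge"):
            fit_ols_cr2(t, "phq9_post", ["trial", "x"], cluster="trial")


class TestLasso:
    @staticmethod
    def _table(seed=0, n=200):
        return generate_trial_pair(
            SyntheticConfig(seed=seed, n_per_trial=(n // 2, n // 2))
        )

    def test_full_shrinkage_at_large_lambda(self):
        t = self._table()
        fit = fit_lasso_interactions(t, ["pseq", "aqol"], [1e6])
        coefs = fit.coef_path[fit.lambda_]
        assert np.allclose(coefs[fit.penalized_mask], 0.0)

    def test_lambda_zero_equals_ols(self):
        t = self._table(1)
        fit = fit_lasso_interactions(t, ["pseq", "aqol"], [0.0])
        names = fit.coef_names
        # rebuild the same design and solve by least squares
        from hetmob.synthetic import moderator_numeric

        cols = []
        for lv in sorted(t["trial"].astype(str).unique()):
            cols.append((t["trial"] == lv).to_numpy(float))
        cols.append(t["phq9_baseline"].to_numpy(float))
        treat = (t["arm"] == "intervention").to_numpy(float)
        cols.append(treat)
        for m in ("pseq", "aqol"):
            x = moderator_numeric(t, m)
            z = (x - x.mean()) / x.std()
            cols.append(z)
            cols.append(treat * z)
        X = np.column_stack(cols)
        beta = np.linalg.lstsq(X, t["phq9_post"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.coef_path[0.0], beta, atol=1e-4)

    def test_orthogonal_soft_threshold_identity(self):
        rng = np.random.default_rng(5)
        n = 400
        t = pd.DataFrame(
            {
                "trial": "t1",
                "arm": "control",  # no treatment variation: interaction = 0 col
                "phq9_baseline": np.zeros(n),
                "pseq": rng.normal(size=n),
            }
        )
        t["phq9_post"] = 0.8 * ((t["pseq"] - t["pseq"].mean()) / t["pseq"].std())
        t["phq9_post"] += rng.normal(0, 0.5, n)
        lam = 0.3
        fit = fit_lasso_interactions(t, ["pseq"], [lam])
        x = t["pseq"].to_numpy()
        z = (x - x.mean()) / x.std()  # population SD, matching the fit
        y = t["phq9_post"].to_numpy()
        yc = y - y.mean()
        ols = float(z @ yc) / n  # x'x/n = 1 by standardization
        expected = np.sign(ols) * max(abs(ols) - lam, 0.0)
        j = fit.coef_names.index("pseq[std]")
        assert fit.coef_path[lam][j] == pytest.approx(expected, abs=1e-8)

    def test_bic_selection_and_sparsity_monotone(self):
        t = self._table(2)
        grid = [0.0, 0.05, 0.2, 1.0, 5.0]
        fit = fit_lasso_interactions(t, ["pseq", "aqol", "nrs_pain"], grid)
        assert fit.bic_path[fit.lambda_] == min(fit.bic_path.values())
        nnz = [fit.n_nonzero(l) for l in sorted(fit.coef_path)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))  # monotone up to ties

    def test_empty_grid_rejected(self, default_table):
        with pytest.raises(ConfigurationError):
            fit_lasso_interactions(default_table, ["pseq"], [])
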