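# Methods

`hetmob` implements a pipeline for exploring heterogeneous treatment
effects in pooled individual-participant data from two randomized trials of
an Internet-based depression intervention for chronic back-pain patients,
with the PHQ-9 at 9-week post-test as the outcome. Every stage is exercised
on synthetic data with planted structure, so all statistical claims made by
the test suite concern recovery of known truths.

## Synthetic study

The generator (`hetmob.synthetic`) emulates the pooled study population:

* **Design.** Two trials (default 252 rows each), plus an external pilot
  trial (n=76). Arm assignment uses largest-remainder apportionment at the
  configured allocation (253/504), so the pooled 253/251 split is exact —
  mimicking a randomization list rather than coin flips.
* **Moderators.** Twenty baseline variables: nine bounded integer scales
  (PHQ-9 0–27, HAM-D-17 0–52, NRS pain 0–10, AQoL-6D 0–100, PSEQ 0–60,
  SPE 0–3, ODI 0–100, Internet-affinity 0–20, age 18–99) and eleven binary
  flags with the pooled observed frequencies (61.31% female, 63.89% prior
  back-pain medication, 69.64% on sick leave, 29.37% online recruitment,
  ...). Continuous scales are truncated normals whose **truncated** moments
  match the configured mean/SD (the parent parameters are found by root
  search); baseline PHQ-9 defaults to mean 10.06, SD 4.55 with a floor of 5
  reflecting the eligibility criterion of at least mild depressive
  symptoms.
* **Correlation.** PHQ-9, HAM-D-17, AQoL-6D and PSEQ load (±0.6) on a
  shared latent severity factor, mapped through the truncated-normal
  quantile so marginals are preserved exactly. Real data show moderator
  intercorrelations up to |r| ≈ 0.7; the single-factor default induces
  pairwise |r| ≈ 0.25–0.4, enough to make moderation analyses non-trivial
  without attempting to match any full correlation matrix.
* **Outcome model.** `phq9_post = a + b·phq9_baseline + trial intercept
  deviation + arm·(d_i·s + trial slope deviation) + noise`, rounded and
  clipped to 0–27. Defaults: intercept a=4, slope b=0.5 (chosen so the
  control arm improves by about one point on average, matching typical
  waitlist drift), residual SD 4.0 (calibrated to a pre–post change-score
  SD near 4.3). Planted subgroup effects d_i are defined by an ordered list
  of covariate predicates that must partition covariate space; the default
  mirrors the six-subgroup tree the analysis is designed to find (cuts at
  PHQ-9 6/10/15, AQoL-6D 43, PSEQ 38, effects −0.55 to −1.31 and +0.24).
* **Effect scale.** Planted d values convert to raw points via the
  configured baseline PHQ-9 SD (`effect_scale_sd`, default 4.55). This is
  deliberate: the estimator standardizes by the pooled observed baseline
  SD, so planted and estimated effects live on the same scale and d-scale
  recovery is exact up to noise. Clipping at the 0 floor attenuates very
  large planted effects by about 0.01–0.03 d.
* **Between-trial heterogeneity.** Trial-level deviations of the control
  mean (τ²=2.2) and the raw-scale treatment effect (τ²=0.48, in squared
  PHQ-9 points) are drawn once per dataset. With only two trials these
  draws dominate seed-to-seed variation of the pooled effect.
* **Missingness.** Only `phq9_post` is masked. P(missing) =
  logistic(c + 0.15·phq9_baseline) with c calibrated by bisection to a 20%
  marginal rate: dropout increases with baseline severity, and depends only
  on fully observed columns — MAR by construction. The machinery supports
  multi-column missingness; the default study masks one column because that
  is the hard part of the estimand (post-test loss to follow-up).

What the generator does **not** emulate: item-level data, floor/ceiling
psychometrics beyond truncation, informative (MNAR) dropout, differential
dropout by arm, site effects within trial, or a realistic full moderator
correlation matrix. Passing tests therefore demonstrate correctness of the
machinery under a known, linear, MAR world — not robustness to violations
of those assumptions.

## Estimation machinery

**MPL mixed model** (`penalized.fit_mpl_lmm`). The one-stage meta-analytic
model maximizes the full Gaussian marginal log-likelihood plus a Wishart
log-prior, `((ν−q−1)/2)·log|G| − tr(S⁻¹G)/2`, on the q×q random-effects
covariance G (default ν=4, S=0.05·I; random design = {trial intercept,
trial×treatment}). The prior is the maximum-a-posteriori device that keeps
G positive-definite away from the boundary — essential with two clusters.
G is parameterized by its Cholesky factor with log-diagonal; β is profiled
out by GLS via a Woodbury decomposition per trial, so each objective
evaluation costs O(G·q²·(q+k)); Nelder–Mead runs to 1e-8 relative objective
change. Fixed-effect covariance is (X'V⁻¹X)⁻¹; Wald tests use a normal
reference because trial-level degrees of freedom are ill-defined with two
clusters. Per-observation scores are xᵢ(V⁻¹r)ᵢ and sum to zero at the
optimum. The implementation was cross-checked against `statsmodels`
MixedLM (ML) under a near-flat prior. Note the prior is *not* innocuous
for variance components: when the residual scale is large relative to the
per-trial information, the trace term shrinks τ² noticeably — the
parameter-recovery test therefore runs at unit residual scale.

**CR2 OLS** (`penalized.fit_ols_cr2`). The sensitivity engine: OLS point
estimates with bias-reduced linearization. The per-cluster adjustment is
the symmetric Moore–Penrose inverse square root of (I−H_gg) — the
pseudo-inverse is required because trial-stratified intercepts make that
matrix singular by construction. Satterthwaite degrees of freedom come
from the homoskedastic working model; they are bounded above by the number
of clusters, yet the resulting interaction test is only mildly
conservative (measured type-I error ≈ 0.037 at α=0.05) because the CR2
variance of a within-cluster contrast is itself small-sample unbiased.
With singleton clusters CR2 reduces exactly to HC2.

**LASSO interaction model** (`penalized.fit_lasso_interactions`).
Coordinate descent on ½n⁻¹‖y−Xβ‖² + λ‖β_pen‖₁ with unpenalized
trial-stratified intercepts, baseline and treatment main effect, and
penalized standardized prognostic and prescriptive (treatment×moderator)
terms. Trial enters as stratified fixed intercepts rather than a random
intercept: with two clusters the two parameterizations coincide up to
shrinkage, and the problem stays a plain convex program. λ is selected by
BIC with degrees of freedom = number of nonzero coefficients; the path is
computed descending with warm starts. At λ=0 the solution matches OLS; in
an orthogonal standardized design each coefficient is exactly the
soft-thresholded OLS estimate.

## Imputation

Groupwise (per-arm) chained equations; predictors pruned below pairwise
|r|=0.05 with trial and arm always retained; visit order by missingness
fraction; m=50 and 10 sweeps by default (reduced in tests and the
acceptance script, where 3 sweeps are visibly past the trace's
stabilization point for single-column missingness). Numeric columns use a
two-level normal model (trial random intercept, MPL/Wishart fit); the
Bayesian step is approximate — β drawn from N(β̂, V̂), σ² from its scaled
inverse-χ², trial intercepts at their empirical-Bayes values — a
simplification of a full posterior draw that is standard in practice.
Categorical columns use predictive mean matching with 5 donors, so imputed
values always come from the observed support. Pooling follows Rubin's
rules with Barnard–Rubin degrees of freedom. For the nonparametric stages
the stack is collapsed to one table: across-imputation means rounded to
the instrument grid (numeric) and modes with first-category tie-break
(categorical); observed cells pass through bit-identically.

## Effect estimation and moderation

Cohen's d divides the adjusted raw-scale difference by the pooled observed
baseline PHQ-9 SD (configurable; nothing in the source material fixes the
standardizer, so the package states its choice and uses it consistently,
including for terminal-node effects). The reliable change index uses
SE_diff = SD_baseline·√(2(1−r)) with test–retest reliability r=0.84 by
default; improvement means RC < −1.96. Arm rates are compared by a
linear-probability contrast pooled across imputations — a pragmatic stand-
in for a mixed-model contrast that is exact for a single table and keeps
the Rubin algebra transparent. Univariate moderation standardizes
continuous moderators (per-SD interaction coefficients) and leaves binary
moderators 0/1 with per-level subgroup effect sizes. The percentile
change-score analysis uses quintile bands with boundary values assigned to
the lower band, per-band/arm change means and SEs, an overall
band×treatment F test and pairwise band contrasts.

## Model-based recursive partitioning

The node model is Gaussian {intercept, treatment}. Instability testing
uses the per-observation score matrix: a supLM statistic over admissible
split fractions for ordered variables, a χ² statistic with k(C−1) degrees
of freedom across categories. supLM p-values come from simulating the
limiting Brownian-bridge supremum at the *actual* candidate split
fractions (10⁴ paths, fixed internal seed, cached per grid); a
Miller–Siegmund crossing-probability formula provides an independent
cross-check for single-parameter processes. Variable selection applies
Bonferroni correction across tested variables at α=0.05 (pre-pruning);
cutpoints minimize the summed child SSE subject to a minimum node size of
20, with "≤ c" read as the largest left-child value; categorical splits
are exhaustive to 10 categories, then outcome-ordered. Setting α=1
disables pre-pruning entirely (saturated growth, variable chosen by
statistic) — used to build deliberately overfit trees for validation
experiments.

Two trials are too few for per-node mixed models, so the "multilevel model
in the nodes" is operationalized as an alternating scheme: (a) a global
MPL model with the tree-implied fixed structure (per-node intercept and
treatment effect), trial-stratified baseline adjustment and random {trial
intercept, trial×treatment}; (b) tree re-growth on the outcome minus the
baseline and empirical-Bayes random-effect contributions; iterate until
node assignments stabilize (cycling between equally supported partitions
also terminates). Removing the prognostic baseline gradient globally is
what makes the node-level instability tests respond to effect
modification rather than to severity gradients; without it the tree
splits on any prognostic variable.

Terminal-node summaries are computed on the **raw** outcome: node models
are plain two-arm means of the node's subset (so a fitted tree predicts
each participant's arm mean within their subgroup), d_i standardizes the
node's treatment coefficient by the training sample's pooled baseline SD,
and reliable-improvement rates are reported per arm. The adjustment stage
steers split selection only. Consequently the tree's R² reflects what the
discovered subgroup structure itself explains — it excludes the baseline
regression, and external transport is penalized by the unseen trial's own
intercept deviation. This is a deliberately conservative prediction
surface; it keeps "terminal d_i equals Cohen's d of the node subset" exact.

## Forest and preselection

300 trees (default) on bootstrap resamples, ⌈p/3⌉ candidate moderators per
tree, pre-pruning as in single trees but without the mixed-effects
alternation (forests run on the aggregated table; the simulated supLM
reference is thinned to 2000 paths there). Importance is the mean
out-of-bag increase in node-model negative log-likelihood after permuting
a moderator's out-of-bag values, one seeded permutation per tree; a
moderator never used in any split has importance exactly zero, and
negative values are preserved. Selection keeps moderators with positive
importance and/or univariate p < 0.05.

## Validation

R² is 1 − SSE/SST (squared correlation available as a sensitivity switch).
Internal validation is bootstrap bias correction with B=1000 by default:
refit the full procedure per resample, optimism = mean(R²_resample −
R²_original-data), adjusted = apparent − optimism; resampling is at the
participant level (trial-stratified resampling available). Failed refits
are excluded and counted; more than 10% aborts. Two regimes of this
estimator are worth knowing: for a *memorizing* procedure the original-
data evaluation leaks in-bag fit, understating optimism; for a heavily
overfit (but non-memorizing) tree the adjusted value lands near the true —
slightly negative — out-of-sample R². The overfitting-detection experiment
therefore uses unpruned trees of moderate depth, where both effects are
small and the adjusted R² sits near zero. External validation routes the
unseen trial through the frozen tree, with no refitting.

## Problem sizes used by the test suite and acceptance script

Calibration experiments use 2000 replications (type-I error bands
0.03–0.07 at α=0.05); structure recovery and null-tree control use 100
seeds at N=504; effect recovery uses 200 seeds; overfitting detection uses
20 seeds with B=200 at n=150; the acceptance script runs the full pipeline
with m=10 imputations, 100 forest trees and B=200. These sizes are the
package's documented defaults for a single-CPU run; the full-scale
defaults (m=50, 300 trees, B=1000) remain the configuration defaults.

## Known limitations

* The Wald normal reference for mixed-model fixed effects is approximate
  with two clusters; the CR2 engine exists as the small-sample check.
* The Bayesian step of the two-level imputation draw is approximate (no
  τ² draw; empirical-Bayes trial intercepts).
* supLM p-values are simulation-based; their resolution is 1/n_paths.
* The alternation for multilevel trees is a heuristic fixed point, not a
  joint likelihood optimization; it can cycle between partitions (handled
  by cycle detection) and is switchable off.
* Bootstrap optimism correction inherits the known biases of the Harrell
  estimator for extremely adaptive procedures (see Validation above).
* Planted-structure recovery at N≈500 has limited power when subgroup
  effects nearly cancel marginally; the recovery experiment plants effects
  only in the stated subgroups for that reason.
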