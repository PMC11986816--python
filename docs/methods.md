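# Methods

`fairscreen` builds risk-based lung-cancer screening (LCS) eligibility
mechanisms that are simultaneously accurate on heavily class-imbalanced
cohorts and unbiased between Black and White smokers. This note documents
the model, the procedure, the synthetic-data generator, and the numerical
and design choices.

## Fairness model and assumptions

Two group-fairness quantities drive the framework:

- **Statistical parity difference (SPD)** — the difference in
  positive-outcome probability between two sensitive groups,
  `SPD = P(Y=1 | G=minority) − P(Y=1 | G=majority)`; 0 indicates parity.
  The sign convention orders levels by ascending frequency (minority
  first); it is overridable.
- **Equal opportunity difference (EOD)** — the difference in true positive
  rates of the eligibility decision, `EOD = TPR(black) − TPR(white)`;
  positive values mean the white group is under-served. EOD is summarized
  as the mean over cross-validation folds or test replicates.

Both are meaningful only under two assumptions the package makes
explicit: (1) the groups' true outcome base rates are not significantly
different (checked with a pooled two-proportion z-test,
`cohort.base_rate_ztest`), and (2) the observed data represent the
population without collection bias. When either fails, a classifier that
satisfies these constraints may still be considered unfair.

## Pipeline

1. **Pre-processing: reweighing.** Each cell of (subgroup, outcome) gets
   weight `w(s, y) = P(s)·P(y) / P(s, y)` with empirical frequencies.
   Under the reweighted distribution the subgroup and the outcome are
   exactly independent, hence the weighted SPD is 0 (to machine
   precision) for every attribute in the spec — this identity is enforced
   by a property test. RW1 uses race alone; RW2 treats the (race, gender)
   tuple as a single compound subgroup, extending group reweighing to
   intersections and guarding against fairness gerrymandering. Empty
   (s, y) cells raise an error naming the cell; no silent smoothing is
   applied, because smoothing changes all weights unpredictably — the
   caller should coarsen the spec instead. Row weights always average
   exactly 1.
2. **Risk model: easy ensemble.** `n_subsets` balanced random
   under-samples of the majority (negative) class, each boosted with
   discrete AdaBoost over depth-limited trees (default: stumps). Stage
   coefficients are `α = learning_rate · ln((1−ε)/ε)`; misclassified
   rows are up-weighted by `exp(α)` and weights renormalized. The
   risk score is the mean over sub-ensembles of the normalized boosted
   margin mapped to [0, 1]. Reweighing weights enter as the boosting's
   initial instance weights; they do not alter the under-sampling
   probabilities (the simplest composition of the two mechanisms;
   switchable in principle, but fixed here). The tuned default
   configuration is 70 sub-ensembles × 200 weak learners at learning
   rate 0.1. A weighted maximum-likelihood logistic model
   (`fit_weighted_logistic`) is the LR baseline.
3. **Post-processing: thresholds.** Decisions follow the global
   convention *eligible iff score ≥ threshold*. `TY` is the Youden
   threshold (max TPR − FPR; ties resolve to the smaller threshold,
   favoring sensitivity). `TU` is the smallest threshold whose
   specificity is at least the empirical specificity of the rule-based
   comparator (2021 USPSTF criteria) on the training rows — the most
   sensitive policy that is not less specific than the rule. "At least"
   semantics were chosen over exact matching because empirical ROC
   specificity is a step function; with a coarse score distribution the
   attained specificity can overshoot the reference.
4. **Model selection.** A grid over {none, RW1, RW2} × {TU, TY} × model
   hyperparameters under seeded stratified 10-fold CV. Per fold and
   configuration, weights, model, and threshold are derived from the
   training folds only; the held-out fold yields AUC and EOD. The
   selected configuration minimizes |mean EOD| among configurations whose
   mean AUC is not significantly below the best (one-sided paired t-test
   across folds at α = 0.05; when the paired test is degenerate a
   non-inferiority margin of 0.01 AUC applies). Ties break by grid
   order. TU is recomputed per fold rather than once on the full
   training set — the leak-free reading of the training protocol.
5. **Testing.** The frozen mechanism is evaluated on replicates of the
   held-out split: stratified subsamples of 80% of each outcome stratum,
   drawn **without replacement**. This m-out-of-n reading of
   "bootstrapping 80% of the test data" makes the degenerate case
   (1 replicate at fraction 1.0) coincide exactly with direct full-split
   evaluation. Replicates missing a class or a group's positives are
   redrawn and counted. Per replicate: sensitivity, specificity, F1 at
   the frozen threshold, AUC overall and per race, and EOD.

## Evaluation statistics

- One-sample two-sided t-test of mean EOD = 0 over the replicate series,
  with the percentile 95% CI.
- Repeated-measures Hedges' g on the paired per-replicate group TPRs:
  `g_rm = J · mean(x−y)/sqrt(s_x² + s_y² − 2 r s_x s_y) · sqrt(2(1−r))`
  with small-sample correction `J = 1 − 3/(4(n−1) − 1)`. Below 0.2 reads
  as small, ~0.5 moderate, above 0.8 large.
- Common-language effect size on the paired differences,
  `Φ(|mean d| / sd d)`; 0.5 means no separation.
- McNemar's test for paired binary eligibility (continuity-corrected χ²,
  exact binomial below 25 discordant pairs). The sensitivity comparison
  against the rule restricts to outcome-positive rows (paired
  eligibility among true cases *is* the sensitivity contrast).
- DeLong's test for correlated AUCs via placement values (structural
  components); single-model AUC variance from the same construction.
  AUC itself equals tie-corrected all-pairs concordance exactly.
- Stratified-bootstrap percentile CIs (resampling within outcome strata,
  preserving class counts).
- Normality screening of EOD series by a Kolmogorov–Smirnov distance
  against a normal with estimated parameters, with a Monte-Carlo
  (Lilliefors-style) null, since the naive KS p-value is anti-conservative
  when parameters are estimated.

## Synthetic cohort generator

The real screening-trial data are access-restricted, so the generator
emulates the structure the framework assumes: outcome prevalence 4.12%,
minority (Black) share 5.74%, near-equal group base rates (4.44% vs
4.10%). Feature marginals are plausible stand-ins, not estimates of any
real cohort: age truncated-normal on the 55–74 enrollment window
(mean 62, sd 5.5); education an ordinal 7-level categorical; BMI normal
(27.3, 4.8); 42% current smokers; packs/day gamma(1.6, 0.45); smoking
start age normal(17.5, 3.5); time since quitting exponential (mean 18 y,
capped by smoking history); pack-years their product; COPD the OR of
bronchitis/emphysema indicators; personal health history the OR of
family-history, prior-cancer, and chest-X-ray indicators.

The outcome is Bernoulli with logistic log-odds `b0_g + x'β`. The
per-group intercepts are calibrated on the realized covariates by
monotone bisection so group base rates converge to their configured
values; `calibrate_intercept` exposes the marginal variant (tolerance
1e-3). The default coefficient vector and the smoking marginals were
fixed once so that two study conditions hold jointly: the generating
model's own AUC is ≈ 0.80 (the oracle the ensemble is measured against)
and the 2021 USPSTF rule attains ≈ 56–58% specificity on unbiased
cohorts, as it does in the population the framework targets.

Bias mechanisms are explicit, composable, and off by default:
`feature_shift` (minority packs/day scaled down while risk is held at the
configured base rate — minority risk partly unexplained by observed
features), `group_intercept` (post-calibration log-odds bump creating a
real base-rate gap), and `differential_label_noise` (minority positives
flipped to negative, emulating differential under-ascertainment). The
stress experiments combine a 35–50% intensity shift with 30–45% label
noise; the milder pair mirrors a realistic degree of data bias, the
stronger pair is a stress condition under which the reweighed
configuration must beat the unweighted one in at least 8 of 10 seeded
worlds.

What passing tests on these cohorts do **not** show: robustness to
feature distributions unlike the stand-ins, to more than two race levels,
to time-to-event structure, or to missing data — none of which the
generator emulates.

## Numerical choices

- ROC curves are exact over all distinct score cut-points; the leading
  (0, 0) point carries an infinite sentinel threshold. Youden ties use a
  1e-12 tolerance: distinct empirical J values differ by at least 1/n²,
  while mathematically equal ones can drift by ~1e-16 through the
  cumulative sums.
- A zero-error weak learner receives the capped coefficient
  `α = learning_rate · ln((1−ε₀)/ε₀)` at ε₀ = 1e-10 instead of infinity;
  boosting stops there, and likewise when ε ≥ 0.5.
- The logistic fit is unpenalized (C = ∞); separation is detected by a
  saturated linear predictor (|lp| > 30) and triggers a weak ridge
  fallback, flagged on the returned model.
- One integer seed governs each operation through hierarchical
  `SeedSequence` splits; identical configuration gives byte-identical
  cohorts and reports.
- Degenerate inputs have documented outputs rather than NaNs: constant
  EOD series (p = 1 or p → 0), zero-variance paired series (g_rm = 0 for
  identical series, error otherwise; CL = 0.5 or 1), zero discordance in
  McNemar (flagged no-test), unreachable reference specificity (maximum
  threshold plus warning flag).

## Problem sizes

Simulation-based checks run at reduced scale chosen as a balance of
statistical resolution and runtime: ensemble-recovery at n = 20 000 with
a 10 × 50 ensemble (the full 70 × 200 configuration is exercised as a
smoke test), and the ten-world bias-mitigation experiment at n = 40 000
with a 6 × 40 ensemble under 10-fold CV. The end-to-end demonstration
script uses n = 30 000 / 20 000 cohorts, a 10 × 60 ensemble, and 200
test replicates. At roughly 4% prevalence and a 5.7% minority share,
per-fold EOD estimates rest on a handful of minority positives; cohort
sizes below ~20 000 leave the fold-level EOD dominated by sampling noise.

## Known limitations

- Reweighing corrects bias expressed as group-outcome dependence; bias
  hidden entirely in feature shifts with equal base rates leaves the
  weights at 1 and is not corrected.
- The easy ensemble's score distribution is discrete (finitely many
  margin values); threshold transfer from training to test can therefore
  overshoot the matched specificity. Larger ensembles smooth the score
  scale.
- Binary sensitive attributes and binary outcomes only; no survival
  structure; no more than the implemented two rule versions (2013/2021).
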