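# fairscreen

Fairness-aware, risk-based **lung cancer screening (LCS) eligibility**.

Rule-based eligibility criteria (USPSTF age/pack-year rules) and risk
models trained on real-world cohorts can under-serve racial groups: the
true positive rate (the chance that a smoker who will develop lung cancer
is offered screening) can differ systematically between Black and White
smokers. `fairscreen` implements a model-agnostic bias-mitigation
framework for this problem, aimed at biostatisticians and screening-policy
researchers working with heavily imbalanced cohorts (~4% outcome
prevalence, ~6% minority share):

- **Reweighing (pre-processing).** Instance weights
  `w(s, y) = P(s)P(y)/P(s, y)` over a sensitive attribute (RW1: race) or
  an intersection (RW2: race × gender) make subgroup and outcome exactly
  independent, driving the weighted statistical parity difference (SPD)
  to zero.
- **Easy-ensemble risk model.** Many balanced random under-samples of
  the majority class, each boosted with AdaBoost stumps
  (`α = lr · ln((1−ε)/ε)`); risk score = mean normalized margin. A
  weighted logistic model is the LR baseline.
- **Threshold policies (post-processing).** `TY`, the Youden threshold
  (max TPR − FPR), and `TU`, the most sensitive threshold whose
  specificity is not below the rule-based comparator's.
- **Evaluation protocol.** Stratified 10-fold CV grid search selecting
  the configuration with the smallest |mean equal opportunity difference
  (EOD)| among those without significantly reduced AUC; test-phase
  replicates with paired t-test on EOD, Hedges' g_rm, common-language
  effect size, McNemar, DeLong, and stratified-bootstrap CIs.

EOD is the fairness criterion throughout:
`EOD = TPR(black) − TPR(white)`, averaged over folds or replicates; 0
means equal opportunity.

Because the real screening-trial data are access-restricted, the package
ships a seeded synthetic-cohort generator emulating their structure
(prevalence, minority share, near-equal base rates, feature schema) with
controllable bias injection, so every claim is testable end to end. See
`docs/methods.md` for the full model description.

## Worked example

```python
from fairscreen import (
    SimConfig, generate_cohort, GridSpec, EecConfig,
    run_grid_search, fit_final, run_test_phase,
)

bias = {"feature_shift": 0.35, "differential_label_noise": 0.3}
train = generate_cohort(SimConfig(n=30_000, seed=1, bias_mechanisms=bias))
test = generate_cohort(SimConfig(n=20_000, seed=2, bias_mechanisms=bias))

grid = GridSpec(thresholds=("TU", "TY"),
                eec_grid=(EecConfig(n_subsets=10, n_weak=60),),
                cv_folds=10, seed=1)
selection = run_grid_search(train, grid)
print(selection.chosen.label)            # EEC_RW1&TU

artifacts = fit_final(train, selection.chosen, seed=3)
report = run_test_phase(artifacts, test, n_boot=200, frac=0.8, seed=4)
print(report.summary_table())
```

On these seeds the grid search selects the race-reweighed ensemble with
the specificity-matched threshold (`EEC_RW1&TU`), with cross-validated
mean AUC 0.786 and |mean EOD| 0.036 versus 0.065 for the matching
no-reweigh configuration. On the held-out cohort the selected mechanism
reaches 80.8% sensitivity at 58.8% specificity, against 74.3% / 58.8%
for the 2021 USPSTF rule — more true cases screened at the same
false-positive burden — while the average EOD improves to −0.106 from
the rule's −0.221 (negative EOD: the minority group is under-served in
this biased world).

A CLI mirrors the library (`fairscreen simulate / train / test /
compare`); every run writes a JSON manifest with its configuration and
seeds.

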