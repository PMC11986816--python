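"""Fairness/accuracy statistics against closed-form and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fairscreen.stats import (
    cl_effect_size,
    confusion_metrics,
    delong_auc_variance,
    delong_test,
    eod,
    eod_ttest,
    group_rates,
    hedges_g_rm,
    ks_normality,
    mcnemar_test,
    stratified_bootstrap_ci,
)


class TestGroupRates:
    def test_hand_counted_toy_table(self):
        group = np.array(list("bbbbbwwwww"))
        labels = np.array([1, 1, 0, 0, 0, 1, 1, 1, 0, 0])
        elig = np.array([1, 0, 1, 0, 0, 1, 1, 0, 0, 1])
        r = group_rates(elig, labels, group)
        assert (r["b"].tp, r["b"].fn, r["b"].fp, r["b"].tn) == (1, 1, 1, 2)
        assert (r["w"].tp, r["w"].fn, r["w"].fp, r["w"].tn) == (2, 1, 1, 1)
        assert r["b"].tpr == pytest.approx(0.5)
        assert r["w"].tpr == pytest.approx(2 / 3)

    def test_all_correct_predictions(self):
        labels = np.array([1, 0, 1, 0])
        r = group_rates(labels, labels, np.array(["b", "b", "w", "w"]))
        for g in ("b", "w"):
            assert r[g].tpr == 1.0 and r[g].fnr == 0.0

    def test_all_negative_predictions(self):
        labels = np.array([1, 0, 1, 0])
        r = group_rates(np.zeros(4), labels, np.array(["b", "b", "w", "w"]))
        for g in ("b", "w"):
            assert r[g].tpr == 0.0 and r[g].specificity == 1.0

    def test_group_without_positives_flagged(self):
        r = group_rates(
            np.array([0, 1]), np.array([0, 1]), np.array(["b", "w"])
        )
        assert r["b"].tpr is None
        assert any("'b'" in f for f in r.flags)


class TestEod:
    @staticmethod
    def rates(tpr_b, tpr_w, n=10):
        elig = np.r_[
            np.ones(int(tpr_b * n)), np.zeros(n - int(tpr_b * n)),
            np.ones(int(tpr_w * n)), np.zeros(n - int(tpr_w * n)),
        ]
        labels = np.ones(2 * n)
        group = np.array(["black"] * n + ["white"] * n)
        return group_rates(elig, labels, group)

    def test_identical_tprs_give_zero(self):
        assert eod(self.rates(0.8, 0.8)) == pytest.approx(0.0)

    def test_sign_convention(self):
        assert eod(self.rates(0.9, 0.8)) == pytest.approx(0.1)
        assert eod(self.rates(0.9, 0.8), ("white", "black")) == pytest.approx(-0.1)

    def test_antisymmetric_under_group_swap(self, rng):
        for _ in range(20):
            r = self.rates(rng.integers(1, 10) / 10, rng.integers(1, 10) / 10)
            assert eod(r) == pytest.approx(-eod(r, ("white", "black")))

    def test_undefined_tpr_rejected(self):
        r = group_rates(np.array([0, 1]), np.array([0, 1]),
                        np.array(["black", "white"]))
        with pytest.raises(ValueError):
            eod(r)


class TestEodTtest:
    def test_all_zero_series(self):
        res = eod_ttest(np.zeros(10))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_closed_form_on_printed_series(self):
        x = np.array([0.01, 0.02, 0.03, 0.02])
        res = eod_ttest(x)
        t_hand = np.mean(x) / (np.std(x, ddof=1) / np.sqrt(4))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=3)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.p == pytest.approx(p_hand, rel=1e-12)
        assert res.mean == pytest.approx(0.02)

    def test_constant_nonzero_series_degenerate(self):
        res = eod_ttest(np.full(6, 0.05))
        assert res.p == 0.0 and np.isinf(res.statistic)
        assert res.note is not None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            eod_ttest(np.array([0.1]))


class TestHedgesGrm:
    def test_identical_series_zero(self):
        x = np.array([0.1, 0.2, 0.3, 0.25])
        assert hedges_g_rm(x, x) == 0.0

    def test_formula_oracle_near_perfect_correlation(self, rng):
        y = rng.normal(size=30)
        x = y + 0.3 + rng.normal(scale=1e-3, size=30)
        got = hedges_g_rm(x, y)
        # independent spreadsheet-style evaluation
        sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        d = np.mean(x - y) / np.sqrt(sx**2 + sy**2 - 2 * r * sx * sy)
        d *= np.sqrt(2 * (1 - r))
        expected = (1 - 3 / (4 * 29 - 1)) * d
        assert got == pytest.approx(expected, rel=1e-12)

    def test_five_pair_toy_series(self):
        x = np.array([0.82, 0.79, 0.85, 0.81, 0.78])
        y = np.array([0.75, 0.77, 0.80, 0.74, 0.76])
        sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        d = np.mean(x - y) / np.sqrt(sx**2 + sy**2 - 2 * r * sx * sy)
        d *= np.sqrt(2 * (1 - r))
        expected = (1 - 3 / (4 * 4 - 1)) * d
        assert hedges_g_rm(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_distinct_means_rejected(self):
        with pytest.raises(ValueError):
            hedges_g_rm(np.array([1.0, 1, 1]), np.array([0.0, 0, 0]))


class TestClEffectSize:
    def test_identical_series(self):
        x = np.array([0.1, 0.5, 0.9])
        assert cl_effect_size(x, x) == 0.5

    def test_unit_standardized_difference(self):
        # differences (0, 1, 2): mean 1, sd 1 -> Phi(1)
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 1.0, 1.0])
        assert cl_effect_size(x, y) == pytest.approx(sps.norm.cdf(1.0))

    def test_four_pair_hand_computation(self):
        x = np.array([0.9, 0.8, 0.85, 0.95])
        y = np.array([0.7, 0.75, 0.8, 0.72])
        d = x - y
        expected = sps.norm.cdf(abs(d.mean()) / d.std(ddof=1))
        assert cl_effect_size(x, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_nonzero_difference(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cl_effect_size(x + 0.5, x) == 1.0


class TestMcnemar:
    def test_identical_classifiers_flagged(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        res = mcnemar_test(a, a)
        assert res.p == 1.0 and "no discordant" in res.note

    def test_continuity_corrected_closed_form(self):
        # b=5, c=15 -> chi2 = (|5-15|-1)^2/20 = 4.05
        a = np.r_[np.ones(5), np.zeros(15), np.ones(30)].astype(bool)
        b = np.r_[np.zeros(5), np.ones(15), np.ones(30)].astype(bool)
        res = mcnemar_test(a, b, exact_below=20)
        assert res.statistic == pytest.approx(4.05)
        assert res.p == pytest.approx(sps.chi2.sf(4.05, 1), rel=1e-12)

    def test_exact_binomial_small_discordance(self):
        # b=1, c=0 -> two-sided exact p = 1.0
        a = np.array([1, 1, 1], dtype=bool)
        b = np.array([0, 1, 1], dtype=bool)
        res = mcnemar_test(a, b)
        assert res.p == 1.0 and "exact" in res.test

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(3)
        a = rng.random(400) < 0.7
        b = rng.random(400) < 0.6
        res = mcnemar_test(a, b)
        bb = int(np.sum(a & ~b))
        cc = int(np.sum(~a & b))
        table = [[0, bb], [cc, 0]]
        ref = sm_mcnemar(table, exact=False, correction=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

        # exact path
        a2 = np.r_[np.ones(3), np.zeros(8), np.ones(50)].astype(bool)
        b2 = np.r_[np.zeros(3), np.ones(8), np.ones(50)].astype(bool)
        res2 = mcnemar_test(a2, b2)
        ref2 = sm_mcnemar([[0, 3], [8, 0]], exact=True)
        assert res2.p == pytest.approx(ref2.pvalue, rel=1e-12)


class TestDelong:
    def test_identical_scores_no_difference(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        res = delong_test(scores, scores, labels)
        assert res.mean == 0.0 and res.p == 1.0

    def test_auc_from_placements_equals_pair_counting(self):
        scores = np.array(
            [0.1, 0.3, 0.3, 0.5, 0.55, 0.6, 0.2, 0.8, 0.85, 0.9, 0.5, 0.7]
        )
        labels = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        auc, _ = delong_auc_variance(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_variance_matches_jackknife_oracle(self, rng):
        n = 200
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = labels * 0.8 + rng.normal(scale=0.7, size=n)

        def auc_of(idx):
            a, _ = delong_auc_variance(scores[idx], labels[idx])
            return a

        _, var = delong_auc_variance(scores, labels)
        # delete-one jackknife variance of the AUC
        loo = np.array([auc_of(np.delete(np.arange(n), i)) for i in range(n)])
        jk_var = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        assert var == pytest.approx(jk_var, rel=0.10)

    def test_two_sided_z_on_shifted_scores(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        good = labels * 1.2 + rng.normal(size=n)
        noise = rng.normal(size=n)
        res = delong_test(good, noise, labels)
        assert res.p < 0.001
        assert res.effect_sizes["auc_a"] > res.effect_sizes["auc_b"]


class TestStratifiedBootstrap:
    @staticmethod
    def frame(rng, n=120):
        return pd.DataFrame(
            {"value": rng.normal(size=n), "outcome": rng.integers(0, 2, n)}
        )

    def test_constant_statistic_zero_width(self, rng):
        ci = stratified_bootstrap_ci(
            lambda df: 3.14, self.frame(rng), n_reps=100, seed=1
        )
        assert ci.lo == ci.hi == 3.14

    def test_fixed_seed_identical(self, rng):
        df = self.frame(rng)
        stat = lambda d: d["value"].mean()
        a = stratified_bootstrap_ci(stat, df, n_reps=150, seed=9)
        b = stratified_bootstrap_ci(stat, df, n_reps=150, seed=9)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_strata_preserve_class_counts(self, rng):
        df = self.frame(rng)
        n1 = int(df["outcome"].sum())

        def stat(d):
            assert int(d["outcome"].sum()) == n1
            return 0.0

        stratified_bootstrap_ci(stat, df, n_reps=100, seed=2)

    def test_failing_replicates_counted(self, rng):
        df = self.frame(rng)
        calls = {"n": 0}

        def stat(d):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return d["value"].mean()

        ci = stratified_bootstrap_ci(stat, df, n_reps=120, seed=3)
        assert ci.n_failed == 40

    def test_coverage_of_sample_mean(self):
        # percentile bootstrap of the mean on normal data: ~95% coverage
        rng = np.random.default_rng(77)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            df = pd.DataFrame(
                {
                    "value": rng.normal(size=80),
                    "outcome": rng.integers(0, 2, 80),
                }
            )
            ci = stratified_bootstrap_ci(
                lambda d: d["value"].mean(), df, n_reps=150,
                seed=int(rng.integers(2**31)),
            )
            hits += ci.lo <= 0.0 <= ci.hi
        assert 0.88 <= hits / n_sim <= 0.99


class TestKsNormality:
    def test_distance_matches_manual_max_gap(self):
        x = np.array([-1.2, -0.4, 0.1, 0.6, 1.4])
        from fairscreen.stats import _ks_distance_to_fitted_normal

        mu, sd = x.mean(), x.std(ddof=1)
        cdf = sps.norm.cdf(np.sort(x), mu, sd)
        gaps = []
        for i, c in enumerate(cdf):
            gaps.append(abs((i + 1) / 5 - c))
            gaps.append(abs(i / 5 - c))
        assert _ks_distance_to_fitted_normal(x) == pytest.approx(max(gaps))

    def test_bimodal_series_rejected(self, rng):
        x = np.r_[rng.normal(-3, 0.4, 100), rng.normal(3, 0.4, 100)]
        res = ks_normality(x, n_mc=400, seed=1)
        assert res.p < 0.05

    def test_normal_series_not_rejected(self, rng):
        res = ks_normality(rng.normal(size=300), n_mc=400, seed=2)
        assert res.p > 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))


def test_confusion_metrics_hand_counts():
    elig = np.array([1, 1, 0, 0, 1])
    labels = np.array([1, 0, 1, 0, 1])
    m = confusion_metrics(elig, labels)
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(1 / 2)
    assert m["f1"] == pytest.approx(4 / (4 + 1 + 1))
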