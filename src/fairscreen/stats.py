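"""Fairness and accuracy statistics for screening-eligibility evaluation.

Implements the full evaluation toolkit: per-group confusion rates, the
equal opportunity difference (EOD = difference in group TPRs), the paired
t-test of mean EOD = 0 with repeated-measures Hedges' g and common-language
effect sizes, McNemar's test for paired binary classifiers, DeLong's test
for correlated AUCs, stratified-bootstrap confidence intervals, and a
Lilliefors-style Kolmogorov-Smirnov normality check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupRates",
    "ComparisonResult",
    "BootstrapCI",
    "group_rates",
    "eod",
    "eod_ttest",
    "hedges_g_rm",
    "cl_effect_size",
    "mcnemar_test",
    "delong_auc_variance",
    "delong_test",
    "stratified_bootstrap_ci",
    "ks_normality",
    "confusion_metrics",
]

DEFAULT_GROUP_ORDER = ("black", "white")


@dataclass
class RateSet:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def tpr(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def fnr(self) -> float | None:
        tpr = self.tpr
        return None if tpr is None else 1.0 - tpr

    @property
    def fpr(self) -> float | None:
        neg = self.fp + self.tn
        return self.fp / neg if neg else None

    @property
    def specificity(self) -> float | None:
        fpr = self.fpr
        return None if fpr is None else 1.0 - fpr


@dataclass
class GroupRates:
    """Confusion-matrix rates per sensitive group."""

    rates: dict[str, RateSet]
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, group: str) -> RateSet:
        return self.rates[group]


@dataclass
class ComparisonResult:
    """A test statistic with p-value and optional effect sizes / CI."""

    test: str
    statistic: float
    p: float
    n: int
    mean: float | None = None
    ci: tuple[float, float] | None = None
    effect_sizes: dict[str, float] = field(default_factory=dict)
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "n": self.n,
            "mean": self.mean,
            "ci": list(self.ci) if self.ci is not None else None,
            "effect_sizes": self.effect_sizes,
            "note": self.note,
        }


def confusion_metrics(eligible: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Sensitivity, specificity and F1 of binary eligibility calls."""
    eligible = np.asarray(eligible)
    labels = np.asarray(labels)
    tp = int(np.sum((eligible == 1) & (labels == 1)))
    fn = int(np.sum((eligible == 0) & (labels == 1)))
    fp = int(np.sum((eligible == 1) & (labels == 0)))
    tn = int(np.sum((eligible == 0) & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


def group_rates(
    eligible: np.ndarray, labels: np.ndarray, group: np.ndarray
) -> GroupRates:
    """Exact per-group confusion-matrix rates.

    A group without positive labels gets an undefined TPR (``None``) and a
    flag rather than an arbitrary value.
    """
    eligible = np.asarray(eligible)
    labels = np.asarray(labels)
    group = np.asarray(group)
    if not len(eligible) == len(labels) == len(group):
        raise ValueError("eligible, labels and group must have equal length")
    out: dict[str, RateSet] = {}
    flags: list[str] = []
    for level in np.unique(group):
        m = group == level
        rs = RateSet(
            tp=int(np.sum(m & (eligible == 1) & (labels == 1))),
            fn=int(np.sum(m & (eligible == 0) & (labels == 1))),
            fp=int(np.sum(m & (eligible == 1) & (labels == 0))),
            tn=int(np.sum(m & (eligible == 0) & (labels == 0))),
        )
        if rs.tpr is None:
            flags.append(f"group {level!r} has no positive labels; TPR undefined")
        out[str(level)] = rs
    return GroupRates(rates=out, flags=flags)


def eod(
    rates: GroupRates, group_order: tuple[str, str] = DEFAULT_GROUP_ORDER
) -> float:
    """Equal opportunity difference: TPR(first group) - TPR(second group).

    The default order (black, white) makes a positive EOD mean the white
    group is under-served (lower TPR).  Antisymmetric under order swap.
    """
    a, b = group_order
    tpr_a, tpr_b = rates[a].tpr, rates[b].tpr
    if tpr_a is None or tpr_b is None:
        raise ValueError("TPR undefined for a group (no positive labels)")
    return tpr_a - tpr_b


def eod_ttest(series: np.ndarray, level: float = 0.95) -> ComparisonResult:
    """One-sample two-sided t-test of mean(EOD) = 0.

    Also reports the series mean and its percentile CI (the series usually
    comes from CV folds or bootstrap replicates).  A zero-variance series
    yields the documented degenerate output instead of a NaN.
    """
    x = np.asarray(series, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 EOD values")
    mean = float(np.mean(x))
    alpha = (1.0 - level) / 2.0
    ci = (
        float(np.percentile(x, 100 * alpha)),
        float(np.percentile(x, 100 * (1 - alpha))),
    )
    if np.ptp(x) == 0.0:  # constant series (robust to fp cancellation)
        if mean == 0.0:
            stat, p, note = 0.0, 1.0, "constant zero series"
        else:
            stat = float(np.sign(mean) * np.inf)
            p, note = 0.0, "constant nonzero series; p -> 0"
        return ComparisonResult(
            test="one-sample t (EOD=0)", statistic=stat, p=p, n=len(x),
            mean=mean, ci=ci, note=note,
        )
    t, p = sps.ttest_1samp(x, 0.0)
    return ComparisonResult(
        test="one-sample t (EOD=0)", statistic=float(t), p=float(p),
        n=len(x), mean=mean, ci=ci,
    )


def hedges_g_rm(x: np.ndarray, y: np.ndarray) -> float:
    """Bias-corrected repeated-measures standardized mean difference.

    d_rm = mean(x - y) / sqrt(s_x^2 + s_y^2 - 2 r s_x s_y) * sqrt(2 (1 - r)),
    multiplied by the small-sample correction J = 1 - 3 / (4 (n - 1) - 1),
    with r the Pearson correlation of the paired series.  Values below 0.2
    read as a small effect, ~0.5 moderate, above 0.8 large.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("paired series must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0.0 and sy == 0.0:
        raise ValueError("zero variance in both series; effect size undefined")
    r = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
    denom_sq = sx**2 + sy**2 - 2.0 * r * sx * sy
    if denom_sq <= 0.0:
        if np.mean(x - y) == 0.0:
            return 0.0  # identical series: no effect
        raise ValueError("zero pooled variance of the paired differences")
    d_rm = np.mean(x - y) / np.sqrt(denom_sq) * np.sqrt(2.0 * (1.0 - r))
    correction = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return float(correction * d_rm)


def cl_effect_size(x: np.ndarray, y: np.ndarray) -> float:
    """Common-language effect size for paired series.

    Phi(|mean(x - y)| / sd(x - y)): the probability that a randomly drawn
    pair shows a difference in the direction of the mean difference; 0.5
    means no separation.  A zero-sd difference returns 1 (deterministic
    separation) or 0.5 (identical series).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired series of equal length >= 2")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0.0:
        return 1.0 if np.mean(d) != 0.0 else 0.5
    return float(sps.norm.cdf(abs(np.mean(d)) / sd))


def mcnemar_test(
    correct_a: np.ndarray, correct_b: np.ndarray, exact_below: int = 25
) -> ComparisonResult:
    """McNemar's test on paired correctness indicators.

    Continuity-corrected chi-square ((|b - c| - 1)^2 / (b + c), 1 df) by
    default; exact two-sided binomial when the discordant count b + c is
    below ``exact_below``.  Zero discordance yields a flagged no-test
    result.
    """
    a = np.asarray(correct_a).astype(bool)
    b_vec = np.asarray(correct_b).astype(bool)
    if len(a) != len(b_vec):
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(a & ~b_vec))
    c = int(np.sum(~a & b_vec))
    disc = b + c
    if disc == 0:
        return ComparisonResult(
            test="mcnemar", statistic=0.0, p=1.0, n=len(a),
            note="no discordant pairs; classifiers identical on this data",
        )
    if disc < exact_below:
        k = min(b, c)
        p = min(1.0, 2.0 * sps.binom.cdf(k, disc, 0.5))
        return ComparisonResult(
            test="mcnemar-exact", statistic=float(k), p=float(p), n=len(a),
            note=f"exact binomial path (b={b}, c={c})",
        )
    chi2 = (abs(b - c) - 1.0) ** 2 / disc
    p = sps.chi2.sf(chi2, df=1)
    return ComparisonResult(
        test="mcnemar-cc", statistic=float(chi2), p=float(p), n=len(a),
        note=f"continuity-corrected (b={b}, c={c})",
    )


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components (placement values) and the AUC.

    V10[i] for positive i = P(score_i > score_neg) with ties half-counted;
    V01[j] analogous for negatives.  mean(V10) = mean(V01) = AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(np.mean(v10))
    return v10, v01, auc


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single score vector."""
    labels = np.asarray(labels)
    v10, v01, auc = _placements(scores, labels)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return auc, float(var)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> ComparisonResult:
    """DeLong's two-sided z-test for two correlated AUCs on the same rows."""
    labels = np.asarray(labels)
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    var = np.var(v10a - v10b, ddof=1) / m + np.var(v01a - v01b, ddof=1) / n
    diff = auc_a - auc_b
    if var <= 0.0:
        return ComparisonResult(
            test="delong", statistic=0.0 if diff == 0 else float("inf"),
            p=1.0 if diff == 0 else 0.0, n=m + n, mean=diff,
            effect_sizes={"auc_a": auc_a, "auc_b": auc_b},
            note="degenerate zero-variance AUC difference",
        )
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return ComparisonResult(
        test="delong", statistic=float(z), p=float(p), n=m + n, mean=diff,
        effect_sizes={"auc_a": auc_a, "auc_b": auc_b},
    )


@dataclass
class BootstrapCI:
    lo: float
    hi: float
    n_failed: int = 0
    values: np.ndarray | None = None

    def __iter__(self):
        return iter((self.lo, self.hi))


def stratified_bootstrap_ci(
    statistic,
    cohort: pd.DataFrame,
    n_reps: int = 500,
    level: float = 0.95,
    seed: int = 0,
    strata_col: str = "outcome",
) -> BootstrapCI:
    """Percentile CI from bootstrap resampling within outcome strata.

    Each replicate resamples rows with replacement separately per stratum
    (preserving class counts) and evaluates ``statistic(replicate_frame)``.
    Replicates where the statistic raises are dropped and counted.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(cohort[strata_col].to_numpy() == v)
              for v in np.unique(cohort[strata_col].to_numpy())]
    values = []
    n_failed = 0
    for _ in range(n_reps):
        idx = np.concatenate(
            [rng.choice(s, size=len(s), replace=True) for s in strata]
        )
        try:
            values.append(float(statistic(cohort.iloc[idx])))
        except Exception:
            n_failed += 1
    if not values:
        raise RuntimeError("statistic failed in every bootstrap replicate")
    values = np.asarray(values)
    alpha = (1.0 - level) / 2.0
    return BootstrapCI(
        lo=float(np.percentile(values, 100 * alpha)),
        hi=float(np.percentile(values, 100 * (1 - alpha))),
        n_failed=n_failed,
        values=values,
    )


def _ks_distance_to_fitted_normal(x: np.ndarray) -> float:
    mu, sd = np.mean(x), np.std(x, ddof=1)
    xs = np.sort(x)
    cdf = sps.norm.cdf(xs, mu, sd)
    n = len(x)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def ks_normality(
    series: np.ndarray, n_mc: int = 1000, seed: int = 0
) -> ComparisonResult:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    The KS distance is computed against a normal with the sample mean and
    sd; because the parameters are estimated, the naive KS p-value is
    anti-conservative, so the null distribution of the distance is
    simulated (Lilliefors-style Monte Carlo, seeded).
    """
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("constant series; normality test undefined")
    d = _ks_distance_to_fitted_normal(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    sims = rng.standard_normal((n_mc, n))
    for i in range(n_mc):
        null[i] = _ks_distance_to_fitted_normal(sims[i])
    p = (1.0 + np.sum(null >= d)) / (n_mc + 1.0)
    return ComparisonResult(
        test="ks-normality (Lilliefors MC)", statistic=d, p=float(p), n=n,
        note=f"{n_mc} Monte-Carlo null replicates",
    )
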