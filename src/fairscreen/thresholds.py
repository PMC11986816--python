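"""ROC-based eligibility thresholds and rule-based screening criteria.

Two post-processing threshold policies convert risk scores into screening
eligibility calls:

``TY``
    The Youden-index threshold: the cut-point maximizing J = TPR - FPR,
    weighting sensitivity and specificity equally.
``TU``
    The specificity-matched threshold: the smallest (most sensitive)
    cut-point whose specificity is at least that of a reference rule-based
    criterion (here, the 2021 USPSTF age/smoking rules), trading extra
    eligibility for no loss in specificity relative to the rule.

The decision convention is fixed globally: eligible iff score >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RocCurve",
    "ThresholdPolicy",
    "roc_curve",
    "auc",
    "youden_threshold",
    "specificity_matched_threshold",
    "uspstf_eligibility",
    "apply_policy",
]


@dataclass
class RocCurve:
    """Exact empirical ROC over every distinct score cut-point.

    Arrays are ordered by descending threshold.  The first point is the
    degenerate "no one eligible" operating point (0, 0), carried with an
    infinite sentinel threshold; the last point is (1, 1) at the minimum
    score.  TPR and FPR are non-increasing in the threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


@dataclass
class ThresholdPolicy:
    """A named decision threshold on [0, 1] risk scores."""

    kind: str  # {"TU", "TY", "fixed"}
    value: float
    reference_specificity: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"TU", "TY", "fixed"}:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"threshold {self.value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "value": self.value,
            "reference_specificity": self.reference_specificity,
            "warning": self.warning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdPolicy":
        return cls(**d)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Empirical ROC under the rule "eligible iff score >= threshold"."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order] == 1
    # Last index of each distinct score block (descending order).
    distinct = np.flatnonzero(np.diff(s) != 0)
    block_ends = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[block_ends]
    fp = np.cumsum(~y)[block_ends]
    thresholds = np.r_[np.inf, s[block_ends]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return RocCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr, n_pos=n_pos, n_neg=n_neg
    )


def auc(curve: RocCurve) -> float:
    """ROC area (trapezoidal; equals tie-corrected all-pairs concordance)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_threshold(curve: RocCurve) -> ThresholdPolicy:
    """Cut-point maximizing J = TPR - FPR; ties go to the smaller threshold.

    The tie rule favors sensitivity, matching the screening emphasis.
    """
    j = curve.tpr - curve.fpr
    # 1e-12 tie tolerance: distinct empirical J values differ by >= 1/n^2,
    # while equal ones can drift by ~1e-16 through the cumulative sums
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # last = smallest threshold
    value = curve.thresholds[best]
    warning = None
    if not np.isfinite(value):
        # Degenerate anti-predictive curve: J maximal only at "no one
        # eligible"; the closest expressible policy on [0, 1] scores.
        value, warning = 1.0, "youden optimum at the empty-eligibility point"
    return ThresholdPolicy(kind="TY", value=float(min(value, 1.0)), warning=warning)


def specificity_matched_threshold(
    curve: RocCurve, reference_specificity: float
) -> ThresholdPolicy:
    """Smallest threshold whose specificity is >= the reference specificity.

    This is the most sensitive policy that is not less specific than the
    reference rule.  If no attainable cut-point reaches the reference, the
    maximum (finite) threshold is returned with a warning flag.
    """
    if not 0.0 <= reference_specificity < 1.0:
        raise ValueError("reference_specificity must be in [0, 1)")
    finite = np.isfinite(curve.thresholds)
    ok = finite & (curve.specificity >= reference_specificity)
    warning = None
    if ok.any():
        idx = np.flatnonzero(ok)[-1]  # descending order: last ok = smallest
    else:
        idx = np.flatnonzero(finite)[0]  # max attainable threshold
        warning = (
            f"reference specificity {reference_specificity:.4f} unattainable; "
            "returning the maximum threshold"
        )
    return ThresholdPolicy(
        kind="TU",
        value=float(min(curve.thresholds[idx], 1.0)),
        reference_specificity=reference_specificity,
        warning=warning,
    )


_USPSTF_RULES = {
    2013: {"age_min": 55, "age_max": 80, "pack_years": 30, "quit_within": 15},
    2021: {"age_min": 50, "age_max": 80, "pack_years": 20, "quit_within": 15},
}


def uspstf_eligibility(rows: pd.DataFrame, version: int = 2021) -> np.ndarray:
    """Rule-based screening eligibility (USPSTF criteria).

    2013: age 55-80, >= 30 pack-years, current smoker or quit <= 15 years ago.
    2021: age 50-80, >= 20 pack-years, same recency clause.
    """
    if version not in _USPSTF_RULES:
        raise ValueError(f"unknown USPSTF version {version}")
    rule = _USPSTF_RULES[version]
    required = ["age", "pack_years", "smoking_status", "years_since_quit"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"rows missing required fields {missing}")
    age = rows["age"].to_numpy(dtype=float)
    py = rows["pack_years"].to_numpy(dtype=float)
    current = rows["smoking_status"].to_numpy() == "current"
    ysq = rows["years_since_quit"].to_numpy(dtype=float)
    eligible = (
        (age >= rule["age_min"])
        & (age <= rule["age_max"])
        & (py >= rule["pack_years"])
        & (current | (ysq <= rule["quit_within"]))
    )
    return eligible.astype(np.int64)


def apply_policy(scores: np.ndarray, policy: ThresholdPolicy) -> np.ndarray:
    """Eligibility calls: eligible iff score >= policy.value."""
    scores = np.asarray(scores, dtype=np.float64)
    return (scores >= policy.value).astype(np.int64)
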