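"""Training and testing protocol orchestration.

Training: a grid search over {no-reweigh, RW1, RW2} x {TU, TY} x model
hyperparameters under stratified k-fold cross-validation.  Per fold and
configuration, reweighing weights, the risk model and the threshold are
all derived from the training folds only; the held-out fold supplies the
AUC and the equal opportunity difference (EOD).  The selected
configuration minimizes |mean EOD| among configurations whose predictive
performance is not significantly below the best (paired across-fold test
at alpha = 0.05, with a non-inferiority margin of 0.01 AUC when the
paired test is degenerate).

Testing: the frozen model and threshold are evaluated on replicates of
the held-out split (stratified subsamples of a configured fraction,
without replacement), yielding per-replicate sensitivity / specificity /
F1 / AUC (overall and per race) and EOD, followed by the full battery of
comparison statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from . import stats as fstats
from .cohort import OUTCOME_COLUMN
from .ensemble import (
    EecConfig,
    EecModel,
    LogisticRiskModel,
    fit_eec,
    fit_weighted_logistic,
    predict_risk,
)
from .reweigh import RW1, RW2, SensitiveSpec, reweigh
from .thresholds import (
    ThresholdPolicy,
    apply_policy,
    auc,
    roc_curve,
    specificity_matched_threshold,
    uspstf_eligibility,
    youden_threshold,
)

__all__ = [
    "GridSpec",
    "PipelineConfig",
    "SelectionResult",
    "TestReport",
    "FittedArtifacts",
    "stratified_kfold",
    "fit_fold",
    "fit_final",
    "run_grid_search",
    "run_test_phase",
    "compare_policies",
    "risk_scores",
]

_PREPROCESS_SPECS: dict[str, SensitiveSpec | None] = {
    "none": None,
    "RW1": RW1,
    "RW2": RW2,
}


@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the training grid."""

    preprocess: str  # {"none", "RW1", "RW2"}
    threshold: str  # {"TU", "TY"}
    model_family: str  # {"EEC", "LR"}
    eec_config: EecConfig | None = None

    def __post_init__(self) -> None:
        if self.preprocess not in _PREPROCESS_SPECS:
            raise ValueError(f"unknown preprocess {self.preprocess!r}")
        if self.threshold not in {"TU", "TY"}:
            raise ValueError(f"unknown threshold {self.threshold!r}")
        if self.model_family not in {"EEC", "LR"}:
            raise ValueError(f"unknown model family {self.model_family!r}")

    @property
    def label(self) -> str:
        base = self.model_family
        if self.preprocess != "none":
            base += f"_{self.preprocess}"
        return f"{base}&{self.threshold}"


@dataclass(frozen=True)
class GridSpec:
    """The training grid and cross-validation protocol."""

    preprocess: tuple[str, ...] = ("none", "RW1", "RW2")
    thresholds: tuple[str, ...] = ("TU", "TY")
    model_families: tuple[str, ...] = ("EEC",)
    eec_grid: tuple[EecConfig, ...] = (EecConfig(),)
    cv_folds: int = 10
    seed: int = 0
    rule_version: int = 2021
    group_order: tuple[str, str] = fstats.DEFAULT_GROUP_ORDER

    def __post_init__(self) -> None:
        if not (self.preprocess and self.thresholds and self.model_families):
            raise ValueError("grid option sets must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def configs(self) -> list[PipelineConfig]:
        out = []
        for fam in self.model_families:
            eec_opts = self.eec_grid if fam == "EEC" else (None,)
            for ec in eec_opts:
                for pre in self.preprocess:
                    for thr in self.thresholds:
                        out.append(
                            PipelineConfig(
                                preprocess=pre, threshold=thr,
                                model_family=fam, eec_config=ec,
                            )
                        )
        return out


@dataclass
class FittedArtifacts:
    """Everything frozen by a training run: model, policy, weights."""

    config: PipelineConfig
    model: EecModel | LogisticRiskModel
    policy: ThresholdPolicy
    reweigh_result: object | None = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.model.save(directory / "model.json")
        (directory / "policy.json").write_text(json.dumps(self.policy.to_dict()))
        meta = {
            "preprocess": self.config.preprocess,
            "threshold": self.config.threshold,
            "model_family": self.config.model_family,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        if self.reweigh_result is not None:
            self.reweigh_result.save(directory / "reweigh.json")

    @classmethod
    def load(cls, directory: str | Path) -> "FittedArtifacts":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        model_text = (directory / "model.json").read_text()
        if meta["model_family"] == "EEC":
            model = EecModel.from_json(model_text)
            config = PipelineConfig(
                preprocess=meta["preprocess"], threshold=meta["threshold"],
                model_family="EEC", eec_config=model.config,
            )
        else:
            model = LogisticRiskModel.from_json(model_text)
            config = PipelineConfig(
                preprocess=meta["preprocess"], threshold=meta["threshold"],
                model_family="LR",
            )
        policy = ThresholdPolicy.from_dict(
            json.loads((directory / "policy.json").read_text())
        )
        return cls(config=config, model=model, policy=policy)


def risk_scores(model, cohort: pd.DataFrame) -> np.ndarray:
    """Dispatch risk prediction for either model family."""
    if isinstance(model, EecModel):
        return predict_risk(model, cohort)
    return model.predict_risk(cohort)


def stratified_kfold(
    cohort: pd.DataFrame, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partition preserving outcome prevalence."""
    y = cohort[OUTCOME_COLUMN].to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each outcome class needs >= {k} rows; counts are {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _fit_model(train: pd.DataFrame, config: PipelineConfig, seed: int):
    """Fit reweighing (if any) and the risk model on training rows only."""
    rw = None
    weights = None
    spec = _PREPROCESS_SPECS[config.preprocess]
    if spec is not None:
        rw = reweigh(train, spec)
        weights = rw.row_weights
    if config.model_family == "EEC":
        ec = config.eec_config or EecConfig()
        ec = EecConfig(
            n_subsets=ec.n_subsets, n_weak=ec.n_weak,
            learning_rate=ec.learning_rate,
            weak_learner_depth=ec.weak_learner_depth, seed=seed,
        )
        model = fit_eec(train, weights=weights, config=ec)
    else:
        model = fit_weighted_logistic(train, weights=weights)
    return model, rw


def _derive_policy(
    train: pd.DataFrame,
    train_scores: np.ndarray,
    threshold_kind: str,
    rule_version: int,
) -> ThresholdPolicy:
    """TY or TU from the training rows' ROC (TU matched to the rule's
    specificity on the same rows)."""
    curve = roc_curve(train_scores, train[OUTCOME_COLUMN].to_numpy())
    if threshold_kind == "TY":
        return youden_threshold(curve)
    rule = uspstf_eligibility(train, version=rule_version)
    neg = train[OUTCOME_COLUMN].to_numpy() == 0
    ref_spec = float(np.mean(rule[neg] == 0))
    return specificity_matched_threshold(curve, ref_spec)


def fit_fold(
    cohort: pd.DataFrame,
    train_idx: np.ndarray,
    config: PipelineConfig,
    seed: int = 0,
    rule_version: int = 2021,
) -> FittedArtifacts:
    """Fit one configuration using only the given training rows.

    All fitted artifacts (weights, model, threshold) depend exclusively on
    ``cohort.iloc[train_idx]``; rows outside the index can be perturbed
    freely without changing the result (no information leak).
    """
    train = cohort.iloc[train_idx].reset_index(drop=True)
    model, rw = _fit_model(train, config, seed)
    scores = risk_scores(model, train)
    policy = _derive_policy(train, scores, config.threshold, rule_version)
    return FittedArtifacts(config=config, model=model, policy=policy,
                           reweigh_result=rw)


def fit_final(
    cohort: pd.DataFrame,
    config: PipelineConfig,
    seed: int = 0,
    rule_version: int = 2021,
) -> FittedArtifacts:
    """Freeze the chosen configuration on the full training split."""
    return fit_fold(cohort, np.arange(len(cohort)), config, seed=seed,
                    rule_version=rule_version)


@dataclass
class ConfigOutcome:
    config: PipelineConfig
    auc_folds: np.ndarray
    eod_folds: np.ndarray  # may contain NaN for folds without group positives
    tu_values: list[float]
    ty_values: list[float]
    eligible: bool = True
    reason: str = ""

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_folds))

    @property
    def mean_eod(self) -> float:
        return float(np.nanmean(self.eod_folds))


@dataclass
class SelectionResult:
    chosen: PipelineConfig
    outcomes: dict[str, ConfigOutcome]
    best_auc_label: str

    def audit_trail(self) -> pd.DataFrame:
        rows = []
        for label, oc in self.outcomes.items():
            rows.append(
                {
                    "config": label,
                    "mean_auc": oc.mean_auc,
                    "mean_eod": oc.mean_eod,
                    "abs_mean_eod": abs(oc.mean_eod),
                    "eligible": oc.eligible,
                    "reason": oc.reason,
                    "selected": label == self.chosen.label,
                }
            )
        return pd.DataFrame(rows)


def run_grid_search(cohort: pd.DataFrame, grid: GridSpec) -> SelectionResult:
    """Cross-validated grid search with fairness-aware model selection.

    For every configuration and fold, pre-processing weights, the model
    and the threshold are fit on the training folds; the held-out fold
    yields the AUC and EOD.  Selection: minimize |mean EOD| among
    configurations whose mean AUC is not significantly lower than the
    best configuration's (paired across-fold comparison at alpha = 0.05;
    non-inferiority margin 0.01 AUC when the paired test is degenerate).
    Ties break by grid order.
    """
    folds = stratified_kfold(cohort, grid.cv_folds, grid.seed)
    y_all = cohort[OUTCOME_COLUMN].to_numpy()
    race_all = cohort["race"].to_numpy()

    # Arms share fitted models across threshold options.
    arms: dict[tuple, dict] = {}
    for fam_i, fam in enumerate(grid.model_families):
        eec_opts = grid.eec_grid if fam == "EEC" else (None,)
        for ec_i, ec in enumerate(eec_opts):
            for pre_i, pre in enumerate(grid.preprocess):
                arm_key = (fam, ec_i, pre)
                aucs, tus, tys = [], [], []
                eods = {"TU": [], "TY": []}
                for fold_i, (tr, te) in enumerate(folds):
                    seed = _derive_seed(grid.seed, fam_i, ec_i, pre_i, fold_i)
                    train = cohort.iloc[tr].reset_index(drop=True)
                    config = PipelineConfig(
                        preprocess=pre, threshold="TY", model_family=fam,
                        eec_config=ec,
                    )
                    model, _ = _fit_model(train, config, seed)
                    train_scores = risk_scores(model, train)
                    held = cohort.iloc[te]
                    held_scores = risk_scores(model, held)
                    aucs.append(
                        auc(roc_curve(held_scores, y_all[te]))
                    )
                    for kind in ("TU", "TY"):
                        policy = _derive_policy(
                            train, train_scores, kind, grid.rule_version
                        )
                        (tus if kind == "TU" else tys).append(policy.value)
                        elig = apply_policy(held_scores, policy)
                        rates = fstats.group_rates(elig, y_all[te], race_all[te])
                        try:
                            eods[kind].append(
                                fstats.eod(rates, grid.group_order)
                            )
                        except (ValueError, KeyError):
                            eods[kind].append(np.nan)
                arms[arm_key] = {
                    "aucs": np.asarray(aucs),
                    "eods": {k: np.asarray(v) for k, v in eods.items()},
                    "tus": tus,
                    "tys": tys,
                    "eec_config": ec,
                }

    outcomes: dict[str, ConfigOutcome] = {}
    for config in grid.configs():
        ec_i = (
            grid.eec_grid.index(config.eec_config)
            if config.model_family == "EEC"
            else 0
        )
        arm = arms[(config.model_family, ec_i, config.preprocess)]
        outcomes[config.label] = ConfigOutcome(
            config=config,
            auc_folds=arm["aucs"],
            eod_folds=arm["eods"][config.threshold],
            tu_values=arm["tus"],
            ty_values=arm["tys"],
        )

    best_label = max(outcomes, key=lambda lb: outcomes[lb].mean_auc)
    best = outcomes[best_label]
    for label, oc in outcomes.items():
        if label == best_label:
            oc.eligible, oc.reason = True, "best mean AUC"
            continue
        diff = oc.auc_folds - best.auc_folds
        if np.std(diff, ddof=1) == 0.0:
            oc.eligible = bool(np.mean(diff) >= -0.01)
            oc.reason = (
                "degenerate paired test; non-inferiority margin 0.01 "
                + ("met" if oc.eligible else "violated")
            )
        else:
            t, p = sps.ttest_rel(oc.auc_folds, best.auc_folds)
            lower = (np.mean(diff) < 0) and (p / 2.0 < 0.05)
            oc.eligible = not lower
            oc.reason = (
                f"paired t vs best: t={t:.3f}, one-sided p={p / 2:.4f}; "
                + ("not significantly lower" if oc.eligible
                   else "significantly lower AUC")
            )

    eligible = [lb for lb, oc in outcomes.items() if oc.eligible]
    if not eligible:
        raise RuntimeError(
            "all configurations excluded; audit: "
            + json.dumps({lb: oc.reason for lb, oc in outcomes.items()})
        )
    grid_order = [c.label for c in grid.configs()]
    chosen_label = min(
        eligible,
        key=lambda lb: (abs(outcomes[lb].mean_eod), grid_order.index(lb)),
    )
    return SelectionResult(
        chosen=outcomes[chosen_label].config,
        outcomes=outcomes,
        best_auc_label=best_label,
    )


def _draw_replicates(
    y: np.ndarray,
    race: np.ndarray,
    n_boot: int,
    frac: float,
    seed: int,
    group_order: tuple[str, str],
    max_redraws: int = 1000,
) -> tuple[list[np.ndarray], int]:
    """Stratified subsample replicates (without replacement) of the test set.

    Each replicate takes round(frac * n) rows per outcome stratum; frac=1.0
    degenerates to the full split.  Replicates missing a class or a group's
    positives are redrawn and counted.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(y == v) for v in (0, 1)]
    replicates: list[np.ndarray] = []
    n_redrawn = 0
    while len(replicates) < n_boot:
        if frac >= 1.0:
            idx = np.concatenate(strata)
        else:
            idx = np.concatenate(
                [
                    rng.choice(s, size=max(1, round(frac * len(s))),
                               replace=False)
                    for s in strata
                ]
            )
        pos_races = set(race[idx][y[idx] == 1])
        if not set(group_order) <= pos_races:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    "could not draw a replicate containing positives for "
                    f"both groups after {max_redraws} redraws"
                )
            continue
        replicates.append(idx)
    return replicates, n_redrawn


@dataclass
class TestReport:
    policy: ThresholdPolicy
    n_boot: int
    frac: float
    n_redrawn: int
    replicates: pd.DataFrame  # per-replicate metrics
    summary: dict
    comparisons: dict[str, fstats.ComparisonResult] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "policy": self.policy.to_dict(),
                "n_boot": self.n_boot,
                "frac": self.frac,
                "n_redrawn": self.n_redrawn,
                "summary": self.summary,
                "comparisons": {
                    k: v.to_dict() for k, v in self.comparisons.items()
                },
            },
            indent=2,
        )

    def summary_table(self) -> str:
        lines = ["| metric | value |", "|---|---|"]
        for k, v in self.summary.items():
            if isinstance(v, float):
                lines.append(f"| {k} | {v:.4f} |")
            else:
                lines.append(f"| {k} | {v} |")
        return "\n".join(lines)


def _replicate_metrics(
    scores: np.ndarray | None,
    eligible_full: np.ndarray,
    y: np.ndarray,
    race: np.ndarray,
    replicates: list[np.ndarray],
    policy: ThresholdPolicy | None,
    group_order: tuple[str, str],
) -> pd.DataFrame:
    rows = []
    for idx in replicates:
        yi, ri = y[idx], race[idx]
        elig = eligible_full[idx]
        met = fstats.confusion_metrics(elig, yi)
        rec: dict[str, float] = dict(met)
        if scores is not None:
            si = scores[idx]
            rec["auc"] = auc(roc_curve(si, yi))
            for g in group_order:
                m = ri == g
                if len(np.unique(yi[m])) == 2:
                    rec[f"auc_{g}"] = auc(roc_curve(si[m], yi[m]))
                else:
                    rec[f"auc_{g}"] = np.nan
        rates = fstats.group_rates(elig, yi, ri)
        rec["eod"] = fstats.eod(rates, group_order)
        for g in group_order:
            rec[f"tpr_{g}"] = rates[g].tpr
        rows.append(rec)
    return pd.DataFrame(rows)


def run_test_phase(
    artifacts: FittedArtifacts,
    test_cohort: pd.DataFrame,
    n_boot: int = 500,
    frac: float = 0.80,
    seed: int = 0,
    rule_version: int = 2021,
    comparator_scores: np.ndarray | None = None,
    group_order: tuple[str, str] = fstats.DEFAULT_GROUP_ORDER,
) -> TestReport:
    """Evaluate frozen artifacts on replicates of the held-out split.

    Per replicate: sensitivity / specificity / F1 at the frozen threshold,
    AUC overall and per race, and the EOD.  Afterwards: the one-sample
    t-test of mean EOD = 0 with Hedges' g_rm and the CL effect size on the
    paired per-replicate group TPRs, McNemar's test against the rule-based
    comparator on the full split, and DeLong's test against
    ``comparator_scores`` (e.g. the logistic baseline) when provided.
    """
    y = test_cohort[OUTCOME_COLUMN].to_numpy()
    race = test_cohort["race"].to_numpy()
    scores = risk_scores(artifacts.model, test_cohort)
    eligible_full = apply_policy(scores, artifacts.policy)

    replicates, n_redrawn = _draw_replicates(
        y, race, n_boot, frac, seed, group_order
    )
    rep = _replicate_metrics(
        scores, eligible_full, y, race, replicates, artifacts.policy, group_order
    )

    comparisons: dict[str, fstats.ComparisonResult] = {}
    eods = rep["eod"].to_numpy()
    if len(eods) >= 2:
        comparisons["eod_ttest"] = fstats.eod_ttest(eods)
    a, b = group_order
    tpr_a = rep[f"tpr_{a}"].to_numpy(dtype=float)
    tpr_b = rep[f"tpr_{b}"].to_numpy(dtype=float)
    if len(rep) >= 3:
        try:
            g_rm = fstats.hedges_g_rm(tpr_a, tpr_b)
        except ValueError:
            g_rm = float("nan")
        cl = fstats.cl_effect_size(tpr_a, tpr_b)
    else:
        g_rm, cl = float("nan"), float("nan")

    rule = uspstf_eligibility(test_cohort, version=rule_version)
    comparisons["mcnemar_vs_rule"] = fstats.mcnemar_test(
        eligible_full == y, rule == y
    )
    # sensitivity comparison: paired eligibility among true positives
    pos = y == 1
    comparisons["mcnemar_sensitivity_vs_rule"] = fstats.mcnemar_test(
        eligible_full[pos] == 1, rule[pos] == 1
    )
    if comparator_scores is not None:
        comparisons["delong_vs_comparator"] = fstats.delong_test(
            scores, comparator_scores, y
        )

    summary = {
        "sensitivity": float(rep["sensitivity"].mean()),
        "specificity": float(rep["specificity"].mean()),
        "f1": float(rep["f1"].mean()),
        "auc": float(rep["auc"].mean()),
        f"auc_{a}": float(rep[f"auc_{a}"].mean(skipna=True)),
        f"auc_{b}": float(rep[f"auc_{b}"].mean(skipna=True)),
        "avg_eod": float(rep["eod"].mean()),
        "eod_ci_lo": float(np.percentile(eods, 2.5)),
        "eod_ci_hi": float(np.percentile(eods, 97.5)),
        "hedges_g_rm": g_rm,
        "cl_effect_size": cl,
        "threshold": artifacts.policy.value,
    }
    return TestReport(
        policy=artifacts.policy,
        n_boot=n_boot,
        frac=frac,
        n_redrawn=n_redrawn,
        replicates=rep,
        summary=summary,
        comparisons=comparisons,
    )


def compare_policies(
    test_cohort: pd.DataFrame,
    policies: list[dict],
    n_boot: int = 500,
    frac: float = 0.80,
    seed: int = 0,
    group_order: tuple[str, str] = fstats.DEFAULT_GROUP_ORDER,
) -> pd.DataFrame:
    """Side-by-side evaluation of eligibility policies on shared replicates.

    Each policy dict has ``name`` and either ``kind="risk"`` with
    ``scores`` (array) and ``policy`` (ThresholdPolicy), or
    ``kind="rule"`` with ``rule_version``.  Rule-based policies get no AUC
    (reported as NaN), mirroring the fact that a binary rule has no
    meaningful ROC.  Replicates are shared across policies so the rows are
    paired.
    """
    if len(policies) < 2:
        raise ValueError("need at least 2 policies to compare")
    y = test_cohort[OUTCOME_COLUMN].to_numpy()
    race = test_cohort["race"].to_numpy()
    replicates, _ = _draw_replicates(y, race, n_boot, frac, seed, group_order)

    rows = []
    for spec in policies:
        name = spec["name"]
        if spec.get("kind", "risk") == "rule":
            eligible_full = uspstf_eligibility(
                test_cohort, version=spec.get("rule_version", 2021)
            )
            scores = None
        else:
            scores = np.asarray(spec["scores"], dtype=np.float64)
            eligible_full = apply_policy(scores, spec["policy"])
        rep = _replicate_metrics(
            scores, eligible_full, y, race, replicates, spec.get("policy"),
            group_order,
        )
        eods = rep["eod"].to_numpy()
        tt = fstats.eod_ttest(eods)
        a, b = group_order
        try:
            g_rm = fstats.hedges_g_rm(rep[f"tpr_{a}"], rep[f"tpr_{b}"])
        except ValueError:
            g_rm = float("nan")
        rows.append(
            {
                "policy": name,
                "sensitivity": rep["sensitivity"].mean(),
                "specificity": rep["specificity"].mean(),
                "f1": rep["f1"].mean(),
                "auc": rep["auc"].mean() if scores is not None else np.nan,
                "avg_eod": tt.mean,
                "eod_ci_lo": tt.ci[0],
                "eod_ci_hi": tt.ci[1],
                "eod_t_p": tt.p,
                "hedges_g_rm": g_rm,
                "cl_effect_size": fstats.cl_effect_size(
                    rep[f"tpr_{a}"], rep[f"tpr_{b}"]
                ),
            }
        )
    return pd.DataFrame(rows)
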