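"""Easy-ensemble risk model for rare-outcome cohorts, plus a weighted
logistic baseline.

The easy ensemble draws many balanced random under-samples of the majority
(outcome-negative) class and boosts a depth-limited decision tree on each
with discrete AdaBoost; the risk score is the mean of the per-sub-ensemble
normalized boosted margins, mapped to [0, 1].  Instance weights from
pre-processing reweighing enter as the boosting's initial weights (they do
not alter the under-sampling probabilities).

Per boosting round with current weights ``w``: fit a tree, compute the
weighted error ``eps``, set the stage coefficient
``alpha = learning_rate * ln((1 - eps) / eps)``, multiply misclassified
instances' weights by ``exp(alpha)`` and renormalize.  Rounds stop early
when ``eps >= 0.5`` (the learner is no better than chance) or ``eps == 0``
(a perfect learner is kept with a capped alpha).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .cohort import FEATURE_COLUMNS

__all__ = [
    "EecConfig",
    "EecModel",
    "BoostedEnsemble",
    "LogisticRiskModel",
    "DegenerateClassError",
    "design_matrix",
    "undersample_balanced",
    "fit_boosted",
    "fit_eec",
    "predict_risk",
    "fit_weighted_logistic",
]

# alpha assigned to a zero-error learner, before learning-rate shrinkage:
# ln((1 - eps)/eps) at eps = 1e-10.
ALPHA_CAP = float(np.log((1.0 - 1e-10) / 1e-10))


class DegenerateClassError(ValueError):
    """Raised when a training (sub)set does not contain both outcome classes."""


@dataclass(frozen=True)
class EecConfig:
    """Easy-ensemble hyperparameters.

    Defaults are the tuned values of the screening-eligibility study:
    70 boosted sub-ensembles of 200 weak learners with learning rate 0.1.
    """

    n_subsets: int = 70
    n_weak: int = 200
    learning_rate: float = 0.1
    weak_learner_depth: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_weak < 1:
            raise ValueError("n_weak must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class _Tree:
    """Array form of a fitted decision tree (JSON-serializable predictor)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray  # predicted class in {-1, +1} per node

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeClassifier) -> "_Tree":
        t = tree.tree_
        votes = t.value[:, 0, :]  # (n_nodes, 2) class weights
        classes = tree.classes_  # sorted, subset of {-1, +1}
        leaf_class = classes[np.argmax(votes, axis=1)].astype(np.int8)
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            leaf_class=leaf_class,
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        active = self.children_left[node] != -1
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
            active = self.children_left[node] != -1
        return self.leaf_class[node].astype(np.float64)

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            leaf_class=np.asarray(d["leaf_class"], dtype=np.int8),
        )


@dataclass
class BoostedEnsemble:
    trees: list[_Tree]
    alphas: np.ndarray
    sampled_indices: np.ndarray | None = None

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Normalized boosted margin in [-1, 1]."""
        agg = np.zeros(len(X))
        for tree, alpha in zip(self.trees, self.alphas):
            agg += alpha * tree.predict(X)
        total = self.alphas.sum()
        return agg / total if total > 0 else agg

    def score(self, X: np.ndarray) -> np.ndarray:
        return 0.5 * (self.margin(X) + 1.0)


@dataclass
class EecModel:
    sub_ensembles: list[BoostedEnsemble]
    feature_names: list[str]
    config: EecConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "fairscreen-eec",
                "version": 1,
                "feature_names": self.feature_names,
                "config": {
                    "n_subsets": self.config.n_subsets,
                    "n_weak": self.config.n_weak,
                    "learning_rate": self.config.learning_rate,
                    "weak_learner_depth": self.config.weak_learner_depth,
                    "seed": self.config.seed,
                },
                "sub_ensembles": [
                    {
                        "alphas": sub.alphas.tolist(),
                        "sampled_indices": (
                            sub.sampled_indices.tolist()
                            if sub.sampled_indices is not None
                            else None
                        ),
                        "trees": [t.to_dict() for t in sub.trees],
                    }
                    for sub in self.sub_ensembles
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EecModel":
        d = json.loads(text)
        if d.get("format") != "fairscreen-eec":
            raise ValueError("not a fairscreen EEC model container")
        subs = [
            BoostedEnsemble(
                trees=[_Tree.from_dict(t) for t in sub["trees"]],
                alphas=np.asarray(sub["alphas"], dtype=np.float64),
                sampled_indices=(
                    np.asarray(sub["sampled_indices"], dtype=np.int64)
                    if sub["sampled_indices"] is not None
                    else None
                ),
            )
            for sub in d["sub_ensembles"]
        ]
        return cls(
            sub_ensembles=subs,
            feature_names=d["feature_names"],
            config=EecConfig(**d["config"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EecModel":
        return cls.from_json(Path(path).read_text())


def design_matrix(
    cohort: pd.DataFrame, feature_names: list[str] | None = None
) -> np.ndarray:
    """Numeric feature matrix; smoking_status is coded current=1, former=0.

    Sensitive attributes (race, gender) are never part of the design: the
    risk model is group-blind by construction.
    """
    names = feature_names or FEATURE_COLUMNS
    missing = [f for f in names if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing feature columns {missing}")
    cols = []
    for name in names:
        if name == "smoking_status":
            cols.append((cohort[name].to_numpy() == "current").astype(np.float64))
        else:
            cols.append(cohort[name].to_numpy(dtype=np.float64))
    return np.column_stack(cols)


def undersample_balanced(y: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """All minority-class rows plus an equal-size uniform subset of the rest.

    Sampling is without replacement and seeded; returns sorted positional
    indices.  With already-balanced classes all rows are returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateClassError("both outcome classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    if len(minority) == len(majority):
        return np.sort(np.concatenate([minority, majority]))
    chosen = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, chosen]))


def fit_boosted(
    X: np.ndarray,
    y: np.ndarray,
    initial_weights: np.ndarray | None,
    config: EecConfig,
) -> BoostedEnsemble:
    """Discrete AdaBoost with learning-rate shrinkage on the stage coefficients.

    ``initial_weights`` (e.g. reweighing weights) seed the instance-weight
    distribution; they are normalized, so scaling them has no effect.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateClassError("boosting subset contains a single class")
    y_pm = np.where(y == 1, 1.0, -1.0)

    if initial_weights is None:
        w = np.full(len(y), 1.0 / len(y))
    else:
        initial_weights = np.asarray(initial_weights, dtype=np.float64)
        if np.any(initial_weights <= 0):
            raise ValueError("initial_weights must be positive")
        w = initial_weights / initial_weights.sum()

    trees: list[_Tree] = []
    alphas: list[float] = []
    for _ in range(config.n_weak):
        learner = DecisionTreeClassifier(
            max_depth=config.weak_learner_depth, random_state=0
        )
        learner.fit(X, y_pm, sample_weight=w)
        pred = learner.predict(X)
        miss = pred != y_pm
        eps = float(w[miss].sum())
        if eps >= 0.5:
            if not trees:
                raise DegenerateClassError(
                    "first weak learner no better than chance; subset degenerate"
                )
            break
        if eps <= 0.0:
            trees.append(_Tree.from_sklearn(learner))
            alphas.append(config.learning_rate * ALPHA_CAP)
            break
        alpha = config.learning_rate * float(np.log((1.0 - eps) / eps))
        trees.append(_Tree.from_sklearn(learner))
        alphas.append(alpha)
        w = w * np.exp(alpha * miss)
        w /= w.sum()
    return BoostedEnsemble(trees=trees, alphas=np.asarray(alphas))


def fit_eec(
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
    config: EecConfig | None = None,
    feature_names: list[str] | None = None,
) -> EecModel:
    """Fit the easy ensemble: n_subsets balanced under-samples, each boosted.

    Sub-ensemble ``i`` draws its under-sample with seed ``config.seed + i``;
    reweighing ``weights`` (if given) are carried into each sub-ensemble as
    the boosting's initial instance weights.
    """
    config = config or EecConfig()
    names = feature_names or FEATURE_COLUMNS
    X = design_matrix(cohort, names)
    y = cohort["outcome"].to_numpy()
    subs = []
    for i in range(config.n_subsets):
        idx = undersample_balanced(y, seed=config.seed + i)
        w0 = weights[idx] if weights is not None else None
        sub = fit_boosted(X[idx], y[idx], w0, config)
        sub.sampled_indices = idx
        subs.append(sub)
    return EecModel(sub_ensembles=subs, feature_names=list(names), config=config)


def predict_risk(model: EecModel, cohort: pd.DataFrame) -> np.ndarray:
    """Risk score in [0, 1]: mean of sub-ensemble scores (normalized margins)."""
    X = design_matrix(cohort, model.feature_names)
    scores = np.zeros(len(X))
    for sub in model.sub_ensembles:
        scores += sub.score(X)
    return scores / len(model.sub_ensembles)


@dataclass
class LogisticRiskModel:
    """Weighted maximum-likelihood logistic risk model (LR baseline)."""

    coef: np.ndarray
    intercept: float
    feature_names: list[str]
    regularized: bool = False
    n_iter: int = 0

    def predict_risk(self, cohort: pd.DataFrame) -> np.ndarray:
        X = design_matrix(cohort, self.feature_names)
        lp = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-lp))

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "fairscreen-logistic",
                "version": 1,
                "feature_names": self.feature_names,
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "regularized": self.regularized,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticRiskModel":
        d = json.loads(text)
        if d.get("format") != "fairscreen-logistic":
            raise ValueError("not a fairscreen logistic model container")
        return cls(
            coef=np.asarray(d["coef"], dtype=np.float64),
            intercept=float(d["intercept"]),
            feature_names=d["feature_names"],
            regularized=bool(d["regularized"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "LogisticRiskModel":
        return cls.from_json(Path(path).read_text())


def fit_weighted_logistic(
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    max_iter: int = 5000,
) -> LogisticRiskModel:
    """Maximum-weighted-likelihood logistic fit (no penalty).

    Duplicating a row is equivalent to doubling its weight.  Under perfect
    separation or non-convergence the fit falls back to a weak ridge
    penalty and the returned model is flagged ``regularized``.
    """
    import warnings

    names = feature_names or FEATURE_COLUMNS
    X = design_matrix(cohort, names)
    y = cohort["outcome"].to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateClassError("logistic fit needs both outcome classes")

    def _fit(C):
        clf = LogisticRegression(
            C=C, solver="lbfgs", max_iter=max_iter, tol=1e-8
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            clf.fit(X, y, sample_weight=weights)
        return clf

    regularized = False
    try:
        clf = _fit(np.inf)  # C=inf: unpenalized maximum likelihood
        lp = X @ clf.coef_[0] + clf.intercept_[0]
        saturated = np.abs(lp).max() > 30.0  # probabilities at 0/1: separation
        if not np.all(np.isfinite(clf.coef_)) or saturated:
            raise ConvergenceWarning("separation or diverging coefficients")
    except (ConvergenceWarning, Warning):
        clf = LogisticRegression(
            C=1e4, solver="lbfgs", max_iter=max_iter, tol=1e-8
        )
        clf.fit(X, y, sample_weight=weights)
        regularized = True
        if not np.all(np.isfinite(clf.coef_)):
            raise RuntimeError(
                "weighted logistic fit failed to converge even with ridge "
                f"fallback after {max_iter} iterations"
            )
    return LogisticRiskModel(
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        feature_names=list(names),
        regularized=regularized,
        n_iter=int(np.max(clf.n_iter_)),
    )
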