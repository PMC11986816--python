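"""Pre-processing bias mitigation by group / intersectional reweighing.

Each (subgroup, outcome) cell gets the weight
``w(s, y) = P(s) * P(y) / P(s, y)`` (expected over observed frequency),
so that under the weighted distribution the sensitive subgroup and the
outcome are statistically independent and the weighted statistical parity
difference (SPD) is exactly zero.  A subgroup ``s`` is a level of a single
sensitive attribute (RW1 convention: race) or a cell of the Cartesian
product of several attributes (RW2: race x gender), which extends group
reweighing to intersectional fairness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OUTCOME_COLUMN

__all__ = [
    "SensitiveSpec",
    "ReweighResult",
    "ReweighError",
    "statistical_parity_difference",
    "reweigh",
    "apply_weights",
    "RW1",
    "RW2",
]

WEIGHT_COLUMN = "weight"


class ReweighError(ValueError):
    """Raised for unusable sensitive-attribute specifications or empty cells."""


@dataclass(frozen=True)
class SensitiveSpec:
    """Ordered sensitive attributes defining subgroups or intersections."""

    attributes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.attributes) < 1:
            raise ReweighError("at least one sensitive attribute required")

    def validate(self, cohort: pd.DataFrame) -> None:
        for attr in self.attributes:
            if attr not in cohort.columns:
                raise ReweighError(f"sensitive attribute {attr!r} not in cohort")
            if cohort[attr].nunique() < 2:
                raise ReweighError(
                    f"sensitive attribute {attr!r} has fewer than 2 observed levels"
                )


RW1 = SensitiveSpec(("race",))
RW2 = SensitiveSpec(("race", "gender"))


@dataclass
class ReweighResult:
    spec: SensitiveSpec
    cell_weights: dict[tuple, float]  # key: (*subgroup levels, outcome)
    row_weights: np.ndarray
    spd_before: dict[str, float] = field(default_factory=dict)
    spd_after: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "attributes": list(self.spec.attributes),
                "cell_weights": [
                    {"cell": [str(k) for k in key[:-1]], "outcome": int(key[-1]),
                     "weight": w}
                    for key, w in sorted(self.cell_weights.items(), key=str)
                ],
                "spd_before": self.spd_before,
                "spd_after": self.spd_after,
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def statistical_parity_difference(
    cohort: pd.DataFrame,
    attr: str,
    weights: np.ndarray | None = None,
    level_order: tuple | None = None,
) -> float:
    """Weighted P(outcome=1 | minority) - P(outcome=1 | majority).

    ``attr`` must be binary.  The default level ordering is minority level
    (ascending weighted frequency, ties broken lexicographically) minus
    majority level; pass ``level_order`` to override.  Zero indicates
    demographic parity.
    """
    g = cohort[attr].to_numpy()
    levels, codes = np.unique(g, return_inverse=True)
    if len(levels) != 2:
        raise ReweighError(f"{attr!r} must be binary, found {len(levels)} levels")
    y = cohort[OUTCOME_COLUMN].to_numpy(dtype=float)
    w = np.ones(len(g)) if weights is None else np.asarray(weights, dtype=float)
    totals = np.bincount(codes, weights=w, minlength=2)
    positives = np.bincount(codes, weights=w * y, minlength=2)
    if level_order is None:
        # np.unique sorts levels, so argsort(kind=stable) on the weighted
        # counts breaks frequency ties lexicographically.
        order = np.argsort(totals, kind="stable")
        level_order = tuple(levels[order])
    rates = {}
    for i, level in enumerate(levels):
        if totals[i] == 0:
            raise ReweighError(f"level {level!r} of {attr!r} has zero total weight")
        rates[level] = positives[i] / totals[i]
    return float(rates[level_order[0]] - rates[level_order[1]])


def reweigh(cohort: pd.DataFrame, spec: SensitiveSpec) -> ReweighResult:
    """Compute demographic-parity reweighing over the spec's intersections.

    Every observed cell of (subgroup, outcome) must be non-empty; an empty
    cell raises rather than being smoothed, since silent smoothing changes
    the weights unpredictably (coarsen the spec instead).  The returned
    row weights have mean exactly 1 and force the weighted SPD of every
    attribute in the spec to zero.
    """
    spec.validate(cohort)
    attrs = list(spec.attributes)
    n = len(cohort)
    y = cohort[OUTCOME_COLUMN]

    # Encode each row's subgroup cell and outcome as integer codes.
    sub_codes, sub_levels = pd.factorize(
        pd.MultiIndex.from_frame(cohort[attrs]) if len(attrs) > 1 else cohort[attrs[0]]
    )
    y_arr = y.to_numpy()
    n_sub = len(sub_levels)

    joint = np.zeros((n_sub, 2))
    np.add.at(joint, (sub_codes, y_arr), 1.0)
    p_sub = joint.sum(axis=1)
    p_y = joint.sum(axis=0)
    expected = np.outer(p_sub, p_y) / n  # expected counts under independence
    missing = np.argwhere((joint == 0) & (p_y > 0))
    if len(missing):
        s_idx, y_idx = missing[0]
        cell = sub_levels[s_idx]
        cell = cell if isinstance(cell, tuple) else (cell,)
        raise ReweighError(
            f"empty (subgroup, outcome) cell: subgroup={cell}, outcome={y_idx}; "
            "coarsen the sensitive spec or supply more data"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        w_cells = np.where(joint > 0, expected / joint, 0.0)

    row_weights = w_cells[sub_codes, y_arr]

    cell_weights: dict[tuple, float] = {}
    for i, cell in enumerate(sub_levels):
        cell = cell if isinstance(cell, tuple) else (cell,)
        for outcome in (0, 1):
            if joint[i, outcome] > 0:
                cell_weights[(*cell, outcome)] = float(w_cells[i, outcome])

    spd_before = {
        a: statistical_parity_difference(cohort, a) for a in attrs
    }
    spd_after = {
        a: statistical_parity_difference(cohort, a, weights=row_weights)
        for a in attrs
    }
    return ReweighResult(
        spec=spec,
        cell_weights=cell_weights,
        row_weights=row_weights,
        spd_before=spd_before,
        spd_after=spd_after,
    )


def apply_weights(cohort: pd.DataFrame, result: ReweighResult) -> pd.DataFrame:
    """Return a copy of the cohort with the reweigh weights as a column.

    Idempotent: re-applying the same result overwrites the same column.
    The input table is not modified.
    """
    if len(result.row_weights) != len(cohort):
        raise ReweighError(
            f"row_weights length {len(result.row_weights)} != cohort size {len(cohort)}"
        )
    out = cohort.copy()
    out[WEIGHT_COLUMN] = result.row_weights
    return out
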