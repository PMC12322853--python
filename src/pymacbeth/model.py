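"""Additive multi-attribute value model: value functions, weights, scoring.

The model follows standard multi-attribute value theory: each criterion *j*
carries a value function mapping performance to a 0-100 attractiveness
score, and a non-negative weight ``w_j`` with ``sum w_j = 1``; the overall
value of a therapy is the weighted sum of its per-criterion scores.

Value functions are piecewise linear through the five (reference level,
scale value) breakpoints produced by the elicitation engine, with the most
attractive level at 100 and the least attractive at 0.  Performance outside
the elicited range is clamped to the nearest anchor value, so overall
scores always stay within [0, 100].

Weights come from qualitative swing weighting: stakeholders compare
hypothetical alternatives, each swinging one criterion from its lower to
its upper reference level while all others stay low, plus an all-lower
baseline.  The MACBETH scale over these alternatives, anchored at the
baseline, is proportional to the criterion weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .elicitation import CardinalScale, derive_scale
from .errors import InvalidInputError
from .judgments import JudgmentMatrix
from .levels import CriterionSpec, ReferenceLevels

__all__ = [
    "ValueFunction",
    "WeightVector",
    "FrameworkModel",
    "ScoreBreakdown",
    "build_value_function",
    "evaluate_value",
    "derive_weights",
    "score_alternative",
    "read_model_json",
    "write_model_json",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ValueFunction:
    """Per-criterion map from performance to a 0-100 value score.

    Numeric criteria use five ``(performance, value)`` breakpoints with
    linear interpolation; categorical criteria use an explicit
    category -> value map.  ``provenance`` records where each piece came
    from (e.g. ``"elicited"``, ``"printed"``, ``"placeholder"``).
    """

    criterion: CriterionSpec
    breakpoints: tuple[tuple[float, float], ...] = ()
    category_map: Mapping[str, float] | None = None
    provenance: str = "elicited"

    def __post_init__(self) -> None:
        if self.criterion.kind == "numeric":
            if self.category_map is not None or len(self.breakpoints) != 5:
                raise InvalidInputError(
                    "numeric value functions need exactly five breakpoints"
                )
            perf = np.array([p for p, _ in self.breakpoints])
            val = np.array([v for _, v in self.breakpoints])
            # breakpoints run L1 (best) .. L5 (worst)
            if not (abs(val[0] - 100.0) < 1e-9 and abs(val[4]) < 1e-9):
                raise InvalidInputError("breakpoint values must be anchored at 100 and 0")
            if np.any(np.diff(val) > 1e-9):
                raise InvalidInputError(
                    "breakpoint values must decrease weakly from L1 to L5"
                )
            d = np.diff(perf)
            if not (np.all(d < 0) or np.all(d > 0)):
                raise InvalidInputError("breakpoint performances must be strictly monotone")
        else:
            if self.category_map is None or not self.category_map:
                raise InvalidInputError("categorical value functions need a category map")

    def __call__(self, x) -> float:
        return evaluate_value(self, x)


def build_value_function(levels: ReferenceLevels, scale: CardinalScale) -> ValueFunction:
    """Attach an elicited cardinal scale to reference levels.

    ``scale`` must be over exactly the items ``L1..L5`` with the anchors at
    L1 = 100 and L5 = 0.
    """
    expected = {f"L{k}" for k in range(1, 6)}
    if set(scale.values) != expected:
        raise InvalidInputError(f"scale items must be exactly {sorted(expected)}")
    if scale.anchors != ("L1", "L5"):
        raise InvalidInputError("scale must be anchored at (L1, L5)")
    vals = [scale.values[f"L{k}"] for k in range(1, 6)]
    if any(vals[k] < vals[k + 1] - 1e-9 for k in range(4)):
        raise InvalidInputError("scale values must decrease weakly from L1 to L5")
    return ValueFunction(
        criterion=levels.criterion,
        breakpoints=tuple(zip(levels.levels, vals)),
    )


def evaluate_value(fn: ValueFunction, x) -> float:
    """Score a performance on one criterion.

    Numeric criteria interpolate linearly between breakpoints and clamp
    outside the elicited range; categorical criteria look the category up.
    """
    if fn.criterion.kind == "categorical":
        if fn.category_map is None or x not in fn.category_map:
            raise InvalidInputError(
                f"unknown category {x!r} for criterion {fn.criterion.id!r}"
            )
        return float(fn.category_map[x])
    x = float(x)
    if not np.isfinite(x):
        raise InvalidInputError("performance must be finite")
    perf = np.array([p for p, _ in fn.breakpoints])
    val = np.array([v for _, v in fn.breakpoints])
    if perf[0] > perf[-1]:  # benefit layout: L1 has the highest performance
        perf, val = perf[::-1], val[::-1]
    return float(np.interp(x, perf, val))


@dataclass(frozen=True)
class WeightVector:
    """Normalized criterion weights (fractions summing to one)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = {str(k): float(v) for k, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        if any(v < 0 for v in w.values()):
            raise InvalidInputError("weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > _WEIGHT_TOL:
            raise InvalidInputError("weights must sum to 1")

    def __getitem__(self, cid: str) -> float:
        return self.weights[cid]

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.weights.items()}


def derive_weights(
    weighting_matrix: JudgmentMatrix,
    criteria_by_alternative: Mapping[str, str],
    baseline: str,
) -> WeightVector:
    """Swing weights from a judgment matrix over hypothetical alternatives.

    Each non-baseline item of the matrix is a hypothetical therapy at the
    upper reference level on one criterion and the lower level elsewhere;
    ``criteria_by_alternative`` maps those item ids to criterion ids.  The
    MACBETH scale anchored at (best swing, baseline) gives each swing a
    value above the baseline proportional to its criterion's weight.
    """
    if baseline not in weighting_matrix.items:
        raise InvalidInputError(f"baseline {baseline!r} is not in the matrix")
    swings = [it for it in weighting_matrix.items if it != baseline]
    if set(criteria_by_alternative) != set(swings):
        raise InvalidInputError(
            "criteria_by_alternative must map exactly the non-baseline items"
        )
    for (i, j), cat in weighting_matrix.judgments.items():
        if cat > 0 and i == baseline:
            raise InvalidInputError(
                f"baseline {baseline!r} judged more attractive than {j!r}"
            )
    # anchor the top at a swing never judged less attractive than any item
    dominated = {j for (i, j), cat in weighting_matrix.judgments.items() if cat > 0}
    candidates = [s for s in swings if s not in dominated]
    if not candidates:
        raise InvalidInputError("no undominated swing alternative to anchor the scale")
    scale = derive_scale(weighting_matrix, top=candidates[0], bottom=baseline)
    raw = np.array([scale.values[s] for s in swings])
    total = raw.sum()
    if total <= 0:
        raise InvalidInputError("all swings are judged equal to the baseline")
    return WeightVector(
        weights={criteria_by_alternative[s]: float(v / total) for s, v in zip(swings, raw)}
    )


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-criterion decomposition of one therapy's overall value."""

    performance: Mapping[str, object]
    values: Mapping[str, float]
    contributions: Mapping[str, float]
    overall: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "criterion_id": cid,
                "performance": self.performance[cid],
                "value_score": self.values[cid],
                "weighted_contribution": self.contributions[cid],
            }
            for cid in self.values
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrameworkModel:
    """A complete scoreable framework: criteria, value functions, weights."""

    criteria: tuple[CriterionSpec, ...]
    value_functions: Mapping[str, ValueFunction]
    weights: WeightVector
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("criterion ids must be unique")
        if set(self.value_functions) != set(ids) or set(self.weights.weights) != set(ids):
            raise InvalidInputError(
                "criteria, value functions and weights must cover the same ids"
            )

    def score(self, performance: Mapping[str, object]) -> ScoreBreakdown:
        return score_alternative(self, performance)


def score_alternative(
    model: FrameworkModel, performance: Mapping[str, object]
) -> ScoreBreakdown:
    """Score one therapy: value each criterion, then take the weighted sum."""
    missing = [c.id for c in model.criteria if c.id not in performance]
    if missing:
        raise InvalidInputError(f"performance missing for criteria: {missing}")
    values = {
        c.id: evaluate_value(model.value_functions[c.id], performance[c.id])
        for c in model.criteria
    }
    contributions = {cid: model.weights[cid] * v for cid, v in values.items()}
    return ScoreBreakdown(
        performance={c.id: performance[c.id] for c in model.criteria},
        values=values,
        contributions=contributions,
        overall=float(sum(contributions.values())),
    )


def _vf_to_dict(fn: ValueFunction) -> dict:
    d: dict = {"provenance": fn.provenance}
    if fn.criterion.kind == "numeric":
        d["levels"] = [p for p, _ in fn.breakpoints]
        d["values"] = [v for _, v in fn.breakpoints]
    else:
        d["category_map"] = dict(fn.category_map)
    return d


def write_model_json(model: FrameworkModel, path: Union[str, Path]) -> None:
    doc = {
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "direction": c.direction,
                "kind": c.kind,
                "units": c.units,
                **_vf_to_dict(model.value_functions[c.id]),
            }
            for c in model.criteria
        ],
        "weights": dict(model.weights.weights),
        "notes": dict(model.notes),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_json(path: Union[str, Path]) -> FrameworkModel:
    doc = json.loads(Path(path).read_text())
    criteria = []
    vfs = {}
    for c in doc["criteria"]:
        spec = CriterionSpec(
            id=c["id"], name=c["name"], direction=c["direction"],
            kind=c["kind"], units=c.get("units", ""),
        )
        criteria.append(spec)
        if spec.kind == "numeric":
            vfs[spec.id] = ValueFunction(
                criterion=spec,
                breakpoints=tuple(zip(c["levels"], c["values"])),
                provenance=c.get("provenance", "elicited"),
            )
        else:
            vfs[spec.id] = ValueFunction(
                criterion=spec,
                category_map=c["category_map"],
                provenance=c.get("provenance", "elicited"),
            )
    return FrameworkModel(
        criteria=tuple(criteria),
        value_functions=vfs,
        weights=WeightVector(doc["weights"]),
        notes=doc.get("notes", {}),
    )
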