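"""Synthetic stakeholder data with known ground truth.

No stakeholder questionnaires or drug performance tables are publicly
deposited, so every engine in this package is exercised against generated
data whose ground truth is known: judgment matrices binned from a true
value scale under fixed category thresholds (always consistent by
construction), ordinal +/-1 perturbations of those judgments, rater panels
with additive Gaussian noise, and uniform drug performance tables.

All generators take an explicit seed; none touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .judgments import JudgmentCategory, JudgmentMatrix
from .levels import CriterionSpec
from .reliability import RatingMatrix

__all__ = [
    "GroundTruth",
    "default_thresholds",
    "generate_consistent_judgments",
    "perturb_judgments",
    "generate_rater_panel",
    "generate_performance_table",
]


def default_thresholds(span: float = 100.0) -> tuple[float, ...]:
    """Six equally spaced category thresholds covering a value span.

    With a 0-100 true scale the seven categories get equal width
    ``span / 7``, so a difference of ``d`` value points falls in category
    ``floor(7 d / span)`` (capped at 6).
    """
    return tuple(span * k / 7.0 for k in range(1, 7))


@dataclass(frozen=True)
class GroundTruth:
    """True item values plus the noise model used to emulate a stakeholder.

    ``flip_probability`` is the chance that a judgment is reported one
    semantic category away from its true bin; ``rater_noise_sd`` is the
    standard deviation of additive rating noise in panel generation.
    """

    values: Mapping[str, float]
    thresholds: tuple[float, ...] = field(default_factory=default_thresholds)
    flip_probability: float = 0.0
    rater_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise InvalidInputError("ground truth needs at least 2 items")
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != 6 or any(t[i + 1] <= t[i] for i in range(5)) or t[0] <= 0:
            raise InvalidInputError("thresholds must be six strictly increasing positives")
        object.__setattr__(self, "thresholds", t)
        if not 0.0 <= self.flip_probability <= 1.0:
            raise InvalidInputError("flip probability must be in [0, 1]")
        if self.rater_noise_sd < 0:
            raise InvalidInputError("rater noise sd must be non-negative")


def _bin_category(diff: float, thresholds: Sequence[float]) -> int:
    """Semantic category of a non-negative true value difference."""
    return int(np.searchsorted(np.asarray(thresholds), diff, side="right"))


def generate_consistent_judgments(truth: GroundTruth) -> JudgmentMatrix:
    """Complete judgment matrix binned from the true values.

    Each pair's category is the threshold bin of the true value difference,
    oriented with the higher-valued item first; the result is consistent by
    construction.  Items are ordered most-attractive-first.

    Distinct true values closer than the first threshold are rejected: they
    would bin as "no difference", which on a cardinal scale means exact
    equality, and mixing that tie with the items' different relations to the
    rest of the scale can make the matrix inconsistent.  Intentional ties
    (exactly equal true values) are fine.
    """
    items = sorted(truth.values, key=lambda it: -truth.values[it])
    judgments: dict[tuple[str, str], JudgmentCategory] = {}
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            i, j = items[a], items[b]
            diff = truth.values[i] - truth.values[j]
            if 0.0 < diff < truth.thresholds[0]:
                raise InvalidInputError(
                    f"items {i!r} and {j!r} differ by {diff:g}, below the first "
                    f"threshold {truth.thresholds[0]:g}: tie them exactly or "
                    "separate them by at least one category width"
                )
            judgments[(i, j)] = JudgmentCategory(_bin_category(diff, truth.thresholds))
    return JudgmentMatrix(items, judgments)


def perturb_judgments(
    matrix: JudgmentMatrix, flip_probability: float, seed: int
) -> JudgmentMatrix:
    """Move each judgment +/-1 category with the given probability.

    The minimal ordinal perturbation: a flipped judgment lands one semantic
    category up or down (clamped to 0..6), emulating a stakeholder who
    mis-grades a difference by one step.  Deterministic for a fixed seed.
    """
    if not 0.0 <= flip_probability <= 1.0:
        raise InvalidInputError("flip probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = {item: k for k, item in enumerate(matrix.items)}
    pairs = sorted(matrix.judgments.items(), key=lambda kv: (idx[kv[0][0]], idx[kv[0][1]]))
    out: dict[tuple[str, str], JudgmentCategory] = {}
    for (i, j), cat in pairs:
        code = int(cat)
        if rng.random() < flip_probability:
            step = 1 if rng.random() < 0.5 else -1
            code = int(np.clip(code + step, 0, 6))
        out[(i, j)] = JudgmentCategory(code)
    return JudgmentMatrix(list(matrix.items), out)


def generate_rater_panel(
    item_means: Sequence[float], rater_noise_sd: float, n_raters: int, seed: int
) -> RatingMatrix:
    """Panel of raters scoring items around true item means with iid noise."""
    if n_raters < 2:
        raise InvalidInputError("need at least 2 raters")
    if rater_noise_sd < 0:
        raise InvalidInputError("rater noise sd must be non-negative")
    means = np.asarray(item_means, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, rater_noise_sd, size=(n_raters, means.size))
    return RatingMatrix(ratings=means[None, :] + noise)


def generate_performance_table(
    criteria: Sequence[CriterionSpec],
    n_drugs: int,
    value_ranges: Mapping[str, tuple[float, float]],
    seed: int,
) -> pd.DataFrame:
    """Uniform drug performance table (drug_id, criterion_id, value)."""
    if n_drugs < 0:
        raise InvalidInputError("n_drugs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in criteria:
        if spec.id not in value_ranges:
            raise InvalidInputError(f"no value range for criterion {spec.id!r}")
        lo, hi = value_ranges[spec.id]
        if not lo < hi or (spec.direction == "harm" and lo < 0):
            raise InvalidInputError(f"invalid range for criterion {spec.id!r}")
        for d in range(n_drugs):
            rows.append(
                {
                    "drug_id": f"drug{d:03d}",
                    "criterion_id": spec.id,
                    "value": float(rng.uniform(lo, hi)),
                }
            )
    return pd.DataFrame(rows, columns=["drug_id", "criterion_id", "value"])
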