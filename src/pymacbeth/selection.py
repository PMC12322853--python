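"""Two-stage criteria selection for the value framework.

Stage one filters a ranked list of candidate criteria by mean stakeholder
importance score (0-5 scale): criteria scoring at or below the threshold
(default 3.5) are dropped.  Stage two applies an explicit audit ledger:
criteria excluded for data availability, redundancy, lack of definition or
confounding, and criteria substituted by an operational proxy (e.g.
health-related quality of life measured as QALYs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "CandidateCriterion",
    "SelectionLedger",
    "ExclusionReason",
    "filter_by_importance",
    "apply_ledger",
    "read_survey_csv",
]

#: Allowed reason categories for an exclusion entry.
ExclusionReason = (
    "below-threshold",
    "data-unavailable",
    "redundant",
    "undefined/unquantifiable",
    "confounded",
)


@dataclass(frozen=True)
class CandidateCriterion:
    """A candidate criterion with its mean stakeholder importance score."""

    name: str
    mean_score: float
    rater_scores: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_score <= 5.0:
            raise InvalidInputError(
                f"mean importance score must be in [0, 5], got {self.mean_score}"
            )
        if self.rater_scores is not None:
            if any(not 0 <= s <= 5 for s in self.rater_scores):
                raise InvalidInputError("rater scores must be integers in 0..5")
            mean = sum(self.rater_scores) / len(self.rater_scores)
            if abs(mean - self.mean_score) > 1e-9:
                raise InvalidInputError(
                    "mean_score must equal the average of rater_scores"
                )


@dataclass(frozen=True)
class SelectionLedger:
    """Audit record of exclusions and substitutions after the score filter."""

    exclusions: tuple[tuple[str, str], ...] = ()  # (criterion name, reason)
    substitutions: tuple[tuple[str, str], ...] = ()  # (original, operational name)

    def __post_init__(self) -> None:
        for name, reason in self.exclusions:
            if reason not in ExclusionReason:
                raise InvalidInputError(
                    f"unknown exclusion reason {reason!r} for {name!r}"
                )
        excluded = {n for n, _ in self.exclusions}
        substituted = {o for o, _ in self.substitutions}
        overlap = excluded & substituted
        if overlap:
            raise InvalidInputError(
                f"criteria cannot be both excluded and substituted: {sorted(overlap)}"
            )


def filter_by_importance(
    candidates: Sequence[CandidateCriterion], threshold: float = 3.5
) -> list[CandidateCriterion]:
    """Keep candidates whose mean importance score exceeds the threshold.

    A score exactly at the threshold is excluded.  Order is preserved.
    """
    if not candidates:
        raise InvalidInputError("candidate list is empty")
    return [c for c in candidates if c.mean_score > threshold]


def apply_ledger(
    retained: Sequence[CandidateCriterion] | Sequence[str],
    ledger: SelectionLedger,
) -> tuple[list[str], pd.DataFrame]:
    """Apply exclusions and substitutions; return final names and audit trail.

    The audit trail has one row per retained criterion with its action
    (``kept`` / ``excluded`` / ``substituted``) and detail.
    """
    names = [c.name if isinstance(c, CandidateCriterion) else str(c) for c in retained]
    known = set(names)
    for name, _ in ledger.exclusions:
        if name not in known:
            raise InvalidInputError(f"exclusion names unknown criterion {name!r}")
    subs = dict(ledger.substitutions)
    for name in subs:
        if name not in known:
            raise InvalidInputError(f"substitution names unknown criterion {name!r}")

    excluded = {n: r for n, r in ledger.exclusions}
    final: list[str] = []
    trail_rows = []
    for name in names:
        if name in excluded:
            trail_rows.append(
                {"criterion": name, "action": "excluded", "detail": excluded[name]}
            )
        elif name in subs:
            final.append(subs[name])
            trail_rows.append(
                {"criterion": name, "action": "substituted", "detail": subs[name]}
            )
        else:
            final.append(name)
            trail_rows.append({"criterion": name, "action": "kept", "detail": ""})
    return final, pd.DataFrame(trail_rows, columns=["criterion", "action", "detail"])


def read_survey_csv(path: Union[str, Path]) -> list[CandidateCriterion]:
    """Read a rater x criterion survey table (first column = rater id).

    Each remaining column is a candidate criterion; cells are integer
    importance scores in 0..5.
    """
    df = pd.read_csv(path, index_col=0)
    candidates = []
    for col in df.columns:
        scores = tuple(int(s) for s in df[col])
        candidates.append(
            CandidateCriterion(
                name=str(col),
                mean_score=sum(scores) / len(scores),
                rater_scores=scores,
            )
        )
    return candidates
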