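"""Performance reference levels per criterion.

Each numeric criterion gets five anchor performances, Level 1 (most
attractive) through Level 5 (least attractive), built from observed drug
performance data.  Levels 2 and 4 are the best and worst observed
performances, Level 3 the median, and Levels 1 and 5 bracket the observed
range by 20 % of the respective extreme, so that any plausible new therapy
falls inside the elicited range.

For *harm* criteria (lower performance is better, e.g. the incidence of
grade 3-4 serious adverse events) Level 2 is the observed minimum and
Level 4 the maximum; for *benefit* criteria (higher is better, e.g. median
progression-free survival) the rule mirrors: Level 2 is the maximum and
Level 4 the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DegenerateRangeError, InvalidInputError

__all__ = [
    "CriterionSpec",
    "PerformanceSample",
    "ReferenceLevels",
    "compute_reference_levels",
    "read_performance_csv",
    "write_levels_csv",
]

Direction = Literal["benefit", "harm"]


@dataclass(frozen=True)
class CriterionSpec:
    """Identity and semantics of one decision criterion."""

    id: str
    name: str
    direction: Direction
    kind: Literal["numeric", "categorical"] = "numeric"
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "harm"):
            raise InvalidInputError(
                f"direction must be 'benefit' or 'harm', got {self.direction!r}"
            )
        if self.kind not in ("numeric", "categorical"):
            raise InvalidInputError(f"kind must be 'numeric' or 'categorical', got {self.kind!r}")


@dataclass(frozen=True)
class PerformanceSample:
    """Observed performance values for one criterion across drugs."""

    criterion: CriterionSpec
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise InvalidInputError("need at least 2 performance values")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("performance values must be finite")
        if self.criterion.direction == "harm" and min(vals) < 0:
            raise InvalidInputError("harm-criterion performances must be non-negative")


@dataclass(frozen=True)
class ReferenceLevels:
    """The ordered quintuple L1..L5, L1 most attractive."""

    criterion: CriterionSpec
    levels: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels, dtype=float)
        if arr.shape != (5,):
            raise InvalidInputError("exactly five reference levels are required")
        diffs = np.diff(arr)
        if self.criterion.direction == "benefit":
            if not np.all(diffs < 0):
                raise InvalidInputError(
                    "benefit levels must strictly decrease from L1 to L5"
                )
        else:
            if not np.all(diffs > 0):
                raise InvalidInputError("harm levels must strictly increase from L1 to L5")

    @property
    def best(self) -> float:
        return self.levels[0]

    @property
    def worst(self) -> float:
        return self.levels[4]


def compute_reference_levels(sample: PerformanceSample) -> ReferenceLevels:
    """Build the five reference levels from observed performance data.

    Raises
    ------
    DegenerateRangeError
        If all observations coincide; a zero-width range cannot yield five
        strictly ordered levels.
    """
    if sample.criterion.kind != "numeric":
        raise InvalidInputError(
            "reference levels from data apply to numeric criteria only; "
            "categorical criteria enumerate their levels in configuration"
        )
    vals = np.asarray(sample.values, dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateRangeError(
            f"criterion {sample.criterion.id!r}: all observations equal {lo}"
        )
    med = float(np.median(vals))
    # a median stuck at an extreme would break strict ordering; use the
    # range midpoint instead
    if med in (lo, hi):
        med = 0.5 * (lo + hi)
    if sample.criterion.direction == "harm":
        levels = (0.8 * lo, lo, med, hi, 1.2 * hi)
    else:
        levels = (1.2 * hi, hi, med, lo, 0.8 * lo)
    return ReferenceLevels(criterion=sample.criterion, levels=levels)


def read_performance_csv(
    path: Union[str, Path], criteria: Sequence[CriterionSpec]
) -> dict[str, PerformanceSample]:
    """Read a long-format performance table (drug_id, criterion_id, value).

    Returns one :class:`PerformanceSample` per criterion id present in both
    the table and ``criteria``.
    """
    df = pd.read_csv(path)
    required = {"drug_id", "criterion_id", "value"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"performance CSV needs columns {sorted(required)}")
    by_id = {c.id: c for c in criteria}
    samples = {}
    for cid, group in df.groupby("criterion_id"):
        if cid in by_id:
            samples[str(cid)] = PerformanceSample(
                criterion=by_id[cid], values=tuple(group["value"].astype(float))
            )
    return samples


def write_levels_csv(levels: Iterable[ReferenceLevels], path: Union[str, Path]) -> None:
    rows = [
        {"criterion_id": rl.criterion.id, "level": k + 1, "performance_value": v}
        for rl in levels
        for k, v in enumerate(rl.levels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
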