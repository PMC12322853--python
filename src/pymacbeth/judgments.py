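"""Qualitative pairwise attractiveness-difference judgments.

A stakeholder compares pairs of items (performance reference levels, or
hypothetical alternatives in swing weighting) and states the *difference of
attractiveness* between the two on a seven-category semantic scale, from
``no`` difference up to ``extreme``.  A collection of such judgments over a
set of items is a :class:`JudgmentMatrix`, the raw input of the MACBETH
elicitation engine.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import InvalidInputError

__all__ = ["JudgmentCategory", "JudgmentMatrix", "read_judgment_csv", "write_judgment_csv"]


class JudgmentCategory(enum.IntEnum):
    """Semantic attractiveness-difference categories, ordered by strength."""

    NO_DIFFERENCE = 0
    VERY_WEAK = 1
    WEAK = 2
    MODERATE = 3
    STRONG = 4
    VERY_STRONG = 5
    EXTREME = 6

    @property
    def label(self) -> str:
        return _CODE_TO_LABEL[int(self)]

    @classmethod
    def parse(cls, value: Union[str, int, "JudgmentCategory"]) -> "JudgmentCategory":
        """Parse a category from an integer code or a case-insensitive label."""
        if isinstance(value, JudgmentCategory):
            return value
        if isinstance(value, (int,)) and not isinstance(value, bool):
            try:
                return cls(value)
            except ValueError:
                raise InvalidInputError(
                    f"judgment category code must be in 0..6, got {value}"
                ) from None
        text = str(value).strip().lower().replace("_", " ")
        if text in _LABEL_TO_CODE:
            return cls(_LABEL_TO_CODE[text])
        try:
            return cls.parse(int(text))
        except (ValueError, InvalidInputError):
            raise InvalidInputError(f"unrecognised judgment category {value!r}") from None


_CODE_TO_LABEL = {
    0: "no",
    1: "very weak",
    2: "weak",
    3: "moderate",
    4: "strong",
    5: "very strong",
    6: "extreme",
}
_LABEL_TO_CODE = {v: k for k, v in _CODE_TO_LABEL.items()}
_LABEL_TO_CODE["no difference"] = 0


@dataclass
class JudgmentMatrix:
    """A partial map of pairwise attractiveness-difference judgments.

    Parameters
    ----------
    items
        Ordered, unique item identifiers (n >= 2).
    judgments
        Map ``(i, j) -> category`` where *i* is the item judged
        not-less-attractive than *j*.  Missing pairs are allowed: the
        engine treats them as unconstrained.

    Notes
    -----
    Cyclic strict preferences are representable here on purpose; they are
    diagnosed by the consistency check rather than rejected at construction,
    mirroring how elicitation software lets a panel enter judgments first
    and validate afterwards.
    """

    items: list[str]
    judgments: dict[tuple[str, str], JudgmentCategory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = [str(i) for i in self.items]
        if len(self.items) < 2:
            raise InvalidInputError("a judgment matrix needs at least 2 items")
        if len(set(self.items)) != len(self.items):
            raise InvalidInputError("item identifiers must be unique")
        item_set = set(self.items)
        seen_pairs: set[frozenset[str]] = set()
        parsed: dict[tuple[str, str], JudgmentCategory] = {}
        for (i, j), cat in self.judgments.items():
            i, j = str(i), str(j)
            if i == j:
                raise InvalidInputError(f"self-judgment on item {i!r} is not allowed")
            if i not in item_set or j not in item_set:
                raise InvalidInputError(f"judgment ({i!r}, {j!r}) names an unknown item")
            key = frozenset((i, j))
            if key in seen_pairs:
                raise InvalidInputError(f"duplicate judgment for pair ({i!r}, {j!r})")
            seen_pairs.add(key)
            parsed[(i, j)] = JudgmentCategory.parse(cat)
        self.judgments = parsed

    @property
    def n_items(self) -> int:
        return len(self.items)

    def category(self, i: str, j: str) -> JudgmentCategory | None:
        """Category for the unordered pair {i, j}, or None if not judged."""
        if (i, j) in self.judgments:
            return self.judgments[(i, j)]
        return self.judgments.get((j, i))

    def without(self, pairs: Iterable[tuple[str, str]]) -> "JudgmentMatrix":
        """A copy with the given judgment pairs removed."""
        drop = {frozenset(p) for p in pairs}
        kept = {
            p: c for p, c in self.judgments.items() if frozenset(p) not in drop
        }
        return JudgmentMatrix(list(self.items), kept)

    def to_frame(self) -> pd.DataFrame:
        """Upper-triangular square table of category labels (blank = missing).

        The serialized layout follows elicitation convention: items are
        listed most-attractive-first, so every judged pair has its preferred
        item on the row.  A strict judgment oriented against the item order
        cannot be written losslessly and raises ``InvalidInputError``.
        """
        df = pd.DataFrame("", index=self.items, columns=self.items, dtype=object)
        order = {item: k for k, item in enumerate(self.items)}
        for (i, j), cat in self.judgments.items():
            if order[i] > order[j] and cat > 0:
                raise InvalidInputError(
                    f"judgment ({i!r} over {j!r}) runs against the item order; "
                    "list items most-attractive-first to serialize"
                )
            r, c = (i, j) if order[i] < order[j] else (j, i)
            df.loc[r, c] = cat.label
        return df


def read_judgment_csv(path: Union[str, Path]) -> JudgmentMatrix:
    """Read a judgment matrix from a square CSV table.

    Header row and index column carry the item identifiers; cell ``(r, c)``
    in the upper triangle is the category (label or 0..6 code) for row item
    vs column item, with the row item not less attractive.  Blank cells are
    missing judgments; the lower triangle is ignored.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    items = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != items:
        raise InvalidInputError("judgment CSV row and column item ids must match")
    judgments: dict[tuple[str, str], JudgmentCategory] = {}
    for a, i in enumerate(items):
        for j in items[a + 1:]:
            cell = str(df.loc[i, j]).strip()
            if cell:
                judgments[(i, j)] = JudgmentCategory.parse(cell)
    return JudgmentMatrix(items, judgments)


def write_judgment_csv(matrix: JudgmentMatrix, path: Union[str, Path]) -> None:
    matrix.to_frame().to_csv(path, index_label="")
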