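"""MACBETH core: ordinal judgments to a cardinal value scale by linear programming.

Given a :class:`~pymacbeth.judgments.JudgmentMatrix`, the engine finds item
values ``v_i >= 0`` and six strictly increasing category thresholds
``t_1 < ... < t_6`` such that every judged pair falls inside the band its
semantic category demands:

* category ``k`` (1..5) on pair ``(i, j)``:  ``t_k <= v_i - v_j <= t_{k+1} - delta``
* category 6: ``v_i - v_j >= t_6``
* category 0 (no difference): ``v_i = v_j``

with ``t_1 >= delta`` and ``t_{k+1} >= t_k + delta`` for a fixed spacing
``delta = 1``.  Feasibility of this system is exactly MACBETH consistency.
For scale derivation the engine minimizes the largest item value and then
lexicographically minimizes the value vector and the thresholds, which makes
the solution unique and the output deterministic; the raw solution is then
affinely rescaled so the chosen anchors sit at 100 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import ConsistencyError, InvalidInputError
from .judgments import JudgmentMatrix

__all__ = [
    "DELTA",
    "CardinalScale",
    "ConsistencyReport",
    "check_consistency",
    "derive_scale",
    "rescale",
]

#: Minimum spacing between consecutive category thresholds (raw LP units).
DELTA = 1.0

#: Numerical tolerance for equality and anchor checks on the 0-100 scale.
TOL = 1e-9


@dataclass(frozen=True)
class CardinalScale:
    """An interval scale over items, plus the category thresholds that fit it.

    ``values`` maps each item to its score; ``anchors`` records which items
    were pinned to the top and bottom of the scale.  ``thresholds`` are the
    six category-boundary differences, a diagnostic of how wide each
    semantic category ended up on the derived scale.
    """

    values: dict[str, float]
    anchors: tuple[str, str]  # (top item, bottom item)
    thresholds: tuple[float, ...]

    def __getitem__(self, item: str) -> float:
        return self.values[item]

    @property
    def top(self) -> str:
        return self.anchors[0]

    @property
    def bottom(self) -> str:
        return self.anchors[1]


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of the consistency check.

    ``witness`` is a set of judged pairs whose joint constraints are
    infeasible; removing them restores feasibility.  It is found greedily
    (largest constraint violation first) and is minimal in the sense that
    the greedy loop stops as soon as the remainder is feasible.
    """

    consistent: bool
    witness: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "consistent": self.consistent,
            "witness": [list(pair) for pair in self.witness],
        }


def _build_system(matrix: JudgmentMatrix, elastic: bool = False):
    """Assemble the LP constraint system.

    Variables: ``[v_0..v_{n-1}, t_1..t_6]`` plus, when ``elastic``, one
    slack per judgment that relaxes all of that judgment's constraints.
    Returns (A_ub, b_ub, n_vars, pairs) where ``pairs`` lists the judged
    item pairs in slack-variable order.
    """
    n = matrix.n_items
    idx = {item: k for k, item in enumerate(matrix.items)}
    pairs = sorted(matrix.judgments.items(), key=lambda kv: (idx[kv[0][0]], idx[kv[0][1]]))
    n_slack = len(pairs) if elastic else 0
    n_vars = n + 6 + n_slack

    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []

    def row() -> np.ndarray:
        return np.zeros(n_vars)

    # threshold spacing: t_1 >= delta, t_{k+1} >= t_k + delta
    r = row()
    r[n] = -1.0
    A_ub.append(r)
    b_ub.append(-DELTA)
    for k in range(5):
        r = row()
        r[n + k] = 1.0
        r[n + k + 1] = -1.0
        A_ub.append(r)
        b_ub.append(-DELTA)

    for p, ((i, j), cat) in enumerate(pairs):
        vi, vj = idx[i], idx[j]
        s = n + 6 + p if elastic else None
        code = int(cat)
        if code == 0:
            # |v_i - v_j| = 0 (<= slack when elastic)
            for sign in (1.0, -1.0):
                r = row()
                r[vi] = sign
                r[vj] = -sign
                if elastic:
                    r[s] = -1.0
                A_ub.append(r)
                b_ub.append(0.0)
        else:
            # lower band edge: v_i - v_j >= t_code
            r = row()
            r[vi] = -1.0
            r[vj] = 1.0
            r[n + code - 1] = 1.0
            if elastic:
                r[s] = -1.0
            A_ub.append(r)
            b_ub.append(0.0)
            if code <= 5:
                # upper band edge: v_i - v_j <= t_{code+1} - delta
                r = row()
                r[vi] = 1.0
                r[vj] = -1.0
                r[n + code] = -1.0
                if elastic:
                    r[s] = -1.0
                A_ub.append(r)
                b_ub.append(-DELTA)

    return np.vstack(A_ub), np.asarray(b_ub), n_vars, [p for p, _ in pairs]


def _solve(c, A_ub, b_ub, extra_rows=None, extra_rhs=None):
    if extra_rows:
        A_ub = np.vstack([A_ub] + [np.atleast_2d(r) for r in extra_rows])
        b_ub = np.concatenate([b_ub, np.asarray(extra_rhs)])
    return linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")


def _is_feasible(matrix: JudgmentMatrix) -> bool:
    A_ub, b_ub, n_vars, _ = _build_system(matrix)
    res = _solve(np.zeros(n_vars), A_ub, b_ub)
    return res.status == 0


def check_consistency(matrix: JudgmentMatrix) -> ConsistencyReport:
    """Decide whether a cardinal scale compatible with all judgments exists.

    Cyclic strict preferences and category bands that cannot be jointly
    honoured both surface here as ``consistent=False``; the witness names a
    small set of judgments whose removal restores feasibility.
    """
    if not matrix.judgments:
        raise InvalidInputError("judgment matrix contains no judgments")
    if _is_feasible(matrix):
        return ConsistencyReport(consistent=True)

    # Greedy repair: relax every judgment with a shared slack, remove the
    # judgment carrying the largest slack, repeat on the remainder.
    witness: list[tuple[str, str]] = []
    current = matrix
    while current.judgments and not _is_feasible(current):
        A_ub, b_ub, n_vars, pairs = _build_system(current, elastic=True)
        n_slack = len(pairs)
        c = np.zeros(n_vars)
        c[-n_slack:] = 1.0
        res = _solve(c, A_ub, b_ub)
        if res.status != 0:  # pragma: no cover - elastic LP is always feasible
            raise RuntimeError("elastic relaxation LP failed to solve")
        slacks = res.x[-n_slack:]
        worst = pairs[int(np.argmax(slacks))]
        witness.append(worst)
        current = current.without([worst])
    return ConsistencyReport(consistent=False, witness=tuple(witness))


def _canonical_solution(matrix: JudgmentMatrix) -> tuple[dict[str, float], tuple[float, ...]]:
    """Canonical raw LP solution: min-max values, then lexicographic min.

    Returns the unique raw value per item and the six raw thresholds.  The
    matrix must already be consistent.
    """
    n = matrix.n_items
    idx = {item: k for k, item in enumerate(matrix.items)}
    A_ub, b_ub, n_vars, _ = _build_system(matrix)

    # Stage 1: minimize the maximum item value (epigraph variable M).
    A1 = np.hstack([A_ub, np.zeros((A_ub.shape[0], 1))])
    rows = []
    for k in range(n):
        r = np.zeros(n_vars + 1)
        r[k] = 1.0
        r[-1] = -1.0
        rows.append(r)
    c = np.zeros(n_vars + 1)
    c[-1] = 1.0
    res = _solve(c, A1, b_ub, extra_rows=rows, extra_rhs=np.zeros(n))
    if res.status != 0:  # pragma: no cover - guarded by consistency check
        raise RuntimeError("scale LP unexpectedly infeasible")
    m_star = float(res.x[-1])

    # Stage 2: lexicographic minimization of v_0, .., v_{n-1}, t_1, .., t_6
    # under v_i <= M*.  Each solved component is locked by an upper bound;
    # the lock slack must clear the solver's feasibility tolerance (1e-7)
    # and the residue is snapped off the final solution below.
    lock_eps = 1e-6
    extra_rows = []
    extra_rhs = []
    for k in range(n):
        r = np.zeros(n_vars)
        r[k] = 1.0
        extra_rows.append(r)
        extra_rhs.append(m_star + lock_eps)
    x = None
    for comp in range(n + 6):
        c = np.zeros(n_vars)
        c[comp] = 1.0
        res = _solve(c, A_ub, b_ub, extra_rows=extra_rows, extra_rhs=extra_rhs)
        if res.status != 0:  # pragma: no cover
            raise RuntimeError("lexicographic LP unexpectedly infeasible")
        x = res.x
        r = np.zeros(n_vars)
        r[comp] = 1.0
        extra_rows.append(r)
        extra_rhs.append(float(x[comp]) + lock_eps)

    x = np.round(x, 6)  # snap off lock slack and solver noise
    raw = {item: float(x[idx[item]]) for item in matrix.items}
    return raw, tuple(float(t) for t in x[n:n + 6])


def derive_scale(matrix: JudgmentMatrix, top: str, bottom: str) -> CardinalScale:
    """Derive the canonical 0-100 cardinal scale from a consistent matrix.

    ``top`` and ``bottom`` are the anchor items mapped exactly to 100 and 0.
    The LP solution is made unique by minimizing the maximum raw value, then
    lexicographically minimizing item values (in item order) and thresholds,
    so repeated calls on the same matrix are bitwise identical.
    """
    if top == bottom:
        raise InvalidInputError("top and bottom anchors must differ")
    for anchor in (top, bottom):
        if anchor not in matrix.items:
            raise InvalidInputError(f"anchor {anchor!r} is not an item of the matrix")
    for (i, j), cat in matrix.judgments.items():
        if cat > 0 and j == top:
            raise InvalidInputError(
                f"top anchor {top!r} is judged less attractive than {i!r}"
            )
        if cat > 0 and i == bottom:
            raise InvalidInputError(
                f"bottom anchor {bottom!r} is judged more attractive than {j!r}"
            )
    report = check_consistency(matrix)
    if not report.consistent:
        raise ConsistencyError("judgment matrix is inconsistent", report=report)

    raw_map, thresholds = _canonical_solution(matrix)
    v_top, v_bot = raw_map[top], raw_map[bottom]
    if v_top - v_bot <= TOL:
        raise InvalidInputError(
            "anchors have equal derived values; choose strictly ordered anchors"
        )
    scale_factor = 100.0 / (v_top - v_bot)
    values = {
        item: float(np.clip((raw_map[item] - v_bot) * scale_factor, 0.0, 100.0))
        for item in matrix.items
    }
    values[top] = 100.0
    values[bottom] = 0.0
    return CardinalScale(
        values=values,
        anchors=(top, bottom),
        thresholds=tuple(float(t * scale_factor) for t in thresholds),
    )


def rescale(scale: CardinalScale, new_top: float, new_bottom: float) -> CardinalScale:
    """Affinely map a scale so its anchors sit at ``new_top`` / ``new_bottom``.

    Ordering and ratios of value differences are preserved.
    """
    if not new_top > new_bottom:
        raise InvalidInputError("new_top must exceed new_bottom")
    old_top = scale.values[scale.top]
    old_bot = scale.values[scale.bottom]
    factor = (new_top - new_bottom) / (old_top - old_bot)
    values = {
        item: new_bottom + (v - old_bot) * factor for item, v in scale.values.items()
    }
    return CardinalScale(
        values=values,
        anchors=scale.anchors,
        thresholds=tuple(t * factor for t in scale.thresholds),
    )
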