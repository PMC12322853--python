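"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP machinery: feasibility is decided
by exhaustive enumeration of integer value assignments on a 0..24 grid,
with category thresholds constructed greedily (an exact construction, since
lowering a threshold only relaxes the upper band edges it governs).
"""

from __future__ import annotations

import itertools

import numpy as np

_GRIDS: dict[int, np.ndarray] = {}


def _grid(n: int, vmax: int = 24) -> np.ndarray:
    if n not in _GRIDS:
        _GRIDS[n] = np.array(
            list(itertools.product(range(vmax + 1), repeat=n)), dtype=np.int32
        )
    return _GRIDS[n]


def brute_force_consistent(items, judgments, vmax: int = 24) -> bool:
    """Does any integer value grid + unit-spaced integer thresholds fit?

    ``judgments`` maps (i, j) -> category code with i not-less-attractive.
    For each candidate value assignment, integer thresholds t_1 < .. < t_6
    are built greedily as small as possible (t_k = max(t_{k-1}+1,
    1 + largest category-(k-1) difference)); the assignment is feasible iff
    every category-k difference is at least t_k.
    """
    n = len(items)
    idx = {it: k for k, it in enumerate(items)}
    V = _grid(n, vmax)
    ok = np.ones(len(V), dtype=bool)
    mins = {k: np.full(len(V), np.inf) for k in range(1, 7)}
    maxs = {k: np.full(len(V), -np.inf) for k in range(1, 7)}
    for (i, j), code in judgments.items():
        d = V[:, idx[i]] - V[:, idx[j]]
        code = int(code)
        if code == 0:
            ok &= d == 0
        else:
            mins[code] = np.minimum(mins[code], d)
            maxs[code] = np.maximum(maxs[code], d)
    t = np.zeros(len(V))
    prev_max = np.full(len(V), -np.inf)
    for k in range(1, 7):
        t = np.maximum(t + 1, prev_max + 1)
        ok &= t <= mins[k]
        prev_max = maxs[k]
    return bool(ok.any())


def random_judgment_case(rng: np.random.Generator, n_max: int = 4):
    """A random small judgment case: (items, judgments dict)."""
    n = int(rng.integers(2, n_max + 1))
    items = [f"i{k}" for k in range(n)]
    judgments = {}
    for a, b in itertools.combinations(items, 2):
        if rng.random() < 0.2:
            continue  # missing pair
        code = int(rng.integers(0, 7))
        if code > 0 and rng.random() < 0.5:
            a, b = b, a
        judgments[(a, b)] = code
    return items, judgments
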