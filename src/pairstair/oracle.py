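"""Exhaustive-search reference for the minimal monotone L1 error.

Independent of the staircase solver: enumerates all labelings of the points
that respect non-strict monotonicity under the componentwise order (in raw,
unoriented coordinates) with branch-and-bound pruning.  Intended for small
instances (n <= 12 or so).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import PairstairError
from .staircase import LabeledPoint, _points_to_arrays


def enumerate_monotone_oracle(points: Sequence[LabeledPoint], p: int) -> float:
    """Exact minimum of sum(w * |f(x) - y|) over all monotone labelings f."""
    x1, x2, y, w = _points_to_arrays(points)
    return enumerate_monotone_oracle_arrays(x1, x2, y, p, w)


def enumerate_monotone_oracle_arrays(x1, x2, y, p, w=None) -> float:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if p < 2:
        raise PairstairError("p must be at least 2")
    if (y < 0).any() or (y >= p).any():
        raise PairstairError(f"labels must lie in 0..{p - 1}")

    # Process points in lexicographic order so that any point dominating
    # another (strictly or not) comes later, except exact duplicates which
    # are constrained in both directions below.
    order = np.lexsort((x2, x1))
    x1, x2, y, w = x1[order], x2[order], y[order], w[order]

    # preds[i]: earlier points dominated by i (force label >= theirs);
    # dups[i]: earlier points with identical coordinates (force equality).
    preds = [
        [j for j in range(i) if x1[j] <= x1[i] and x2[j] <= x2[i]] for i in range(n)
    ]
    dups = [
        [j for j in range(i) if x1[j] == x1[i] and x2[j] == x2[i]] for i in range(n)
    ]

    best = float(np.sum(w * np.maximum(y, p - 1 - y)))  # any labeling beats this
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, cost: float):
        nonlocal best
        if cost >= best:
            return
        if i == n:
            best = cost
            return
        lo = 0
        hi = p - 1
        for j in preds[i]:
            lo = max(lo, labels[j])
        for j in dups[i]:
            lo = max(lo, labels[j])
            hi = min(hi, labels[j])
        for lab in range(lo, hi + 1):
            labels[i] = lab
            rec(i + 1, cost + w[i] * abs(lab - y[i]))
        labels[i] = 0

    rec(0, 0.0)
    return best
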