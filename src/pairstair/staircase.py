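"""Exact L1-optimal monotone staircase classifiers on two real features.

The model predicts one of ``p`` ordered classes (0 = worst outcome) and is
monotone nondecreasing in each feature after applying a per-feature sign
(the :class:`Orientation`).  Fitting decomposes the multiclass problem into
binary upper-set problems, one per class threshold, solved exactly by a
dynamic program and combined recursively so that the resulting boundaries
are nested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from ._solver import corners_from_assignment, solve_binary
from .errors import PairstairError


@dataclass(frozen=True)
class LabeledPoint:
    """A weighted training sample: two expression values and an ordinal label."""

    x1: float
    x2: float
    y: int
    w: float = 1.0

    def __post_init__(self):
        if not (math.isfinite(self.x1) and math.isfinite(self.x2)):
            raise PairstairError("point coordinates must be finite")
        if self.w < 0:
            raise PairstairError("point weight must be nonnegative")
        if int(self.y) != self.y or self.y < 0:
            raise PairstairError("label must be a nonnegative integer")


@dataclass(frozen=True)
class Orientation:
    """Per-feature signs; the predicted label is nondecreasing in s1*x1 and s2*x2."""

    s1: int
    s2: int

    def __post_init__(self):
        if self.s1 not in (1, -1) or self.s2 not in (1, -1):
            raise PairstairError("orientation signs must be +1 or -1")

    def apply(self, x1, x2):
        return self.s1 * np.asarray(x1), self.s2 * np.asarray(x2)

    def to_list(self):
        return [self.s1, self.s2]


#: Canonical tie-break order for orientation search.
ORIENTATIONS = (
    Orientation(1, 1),
    Orientation(1, -1),
    Orientation(-1, 1),
    Orientation(-1, -1),
)


@dataclass(frozen=True)
class UpperSetBoundary:
    """An upper set given by its corner antichain, in oriented coordinates.

    A point belongs to the upper set iff it dominates (>= in both oriented
    coordinates) at least one corner.  The whole plane is encoded by a single
    corner at (-inf, -inf); the empty set by an empty corner list.
    """

    corners: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        for a in self.corners:
            for b in self.corners:
                if a is not b and a[0] >= b[0] and a[1] >= b[1]:
                    raise PairstairError("corners must form an antichain")

    def contains(self, u1, u2):
        """Vectorized membership test in oriented coordinates."""
        u1 = np.asarray(u1, dtype=float)
        u2 = np.asarray(u2, dtype=float)
        out = np.zeros(np.broadcast(u1, u2).shape, dtype=bool)
        for c1, c2 in self.corners:
            out |= (u1 >= c1) & (u2 >= c2)
        return out

    def issubset(self, other: "UpperSetBoundary") -> bool:
        """True if this upper set is contained in ``other``."""
        if not self.corners:
            return True
        if not other.corners:
            return False
        return all(
            any(c1 >= d1 and c2 >= d2 for d1, d2 in other.corners)
            for c1, c2 in self.corners
        )


@dataclass(frozen=True)
class Region:
    """Constraint for a binary fit: the upper set must contain ``outer`` and
    lie within ``inner`` (either may be None)."""

    outer: Optional[UpperSetBoundary] = None
    inner: Optional[UpperSetBoundary] = None


@dataclass(frozen=True)
class BinaryFit:
    boundary: UpperSetBoundary
    error: float
    in_upper: np.ndarray = field(compare=False)


def _points_to_arrays(points: Sequence[LabeledPoint]):
    if len(points) == 0:
        raise PairstairError("at least one point is required")
    x1 = np.array([p.x1 for p in points], dtype=float)
    x2 = np.array([p.x2 for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=np.int64)
    w = np.array([p.w for p in points], dtype=float)
    return x1, x2, y, w


def fit_binary_upper_set(
    points: Sequence[LabeledPoint],
    region: Optional[Region] = None,
    orientation: Orientation = Orientation(1, 1),
) -> BinaryFit:
    """Fit the L1-optimal monotone upper set for 0/1-labeled points.

    Among all optimal upper sets (optionally constrained by ``region``) the
    smallest one is returned; see :mod:`pairstair._solver`.
    """
    x1, x2, y, w = _points_to_arrays(points)
    if not np.isin(y, (0, 1)).all():
        raise PairstairError("binary fit requires labels in {0, 1}")
    o1, o2 = orientation.apply(x1, x2)
    force = None
    if region is not None:
        force = np.zeros(y.size, dtype=np.int8)
        if region.outer is not None:
            force[region.outer.contains(o1, o2)] = 1
        if region.inner is not None:
            force[~region.inner.contains(o1, o2)] = -1
    err, in_up = solve_binary(o1, o2, y, w, force)
    return BinaryFit(UpperSetBoundary(corners_from_assignment(o1, o2, in_up)), err, in_up)


@dataclass(frozen=True)
class StaircaseModel:
    """Fitted monotone multi-class decision function on two oriented features.

    ``boundaries[t-1]`` delimits predicted class >= t; upper sets are nested
    (boundary t+1 inside boundary t), which makes prediction monotone.
    """

    p: int
    orientation: Orientation
    boundaries: Tuple[UpperSetBoundary, ...]
    training_error: float

    def __post_init__(self):
        if self.p < 2:
            raise PairstairError("p must be at least 2")
        if len(self.boundaries) != self.p - 1:
            raise PairstairError("need exactly p-1 boundaries")
        for lo, hi in zip(self.boundaries[1:], self.boundaries[:-1]):
            if not lo.issubset(hi):
                raise PairstairError("boundaries must be nested")

    def predict(self, x1, x2):
        """Largest t whose upper set contains the oriented point (0 if none)."""
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
            raise PairstairError("prediction inputs must be finite")
        scalar = x1.ndim == 0 and x2.ndim == 0
        u1, u2 = self.orientation.apply(np.atleast_1d(x1), np.atleast_1d(x2))
        out = np.zeros(np.broadcast(u1, u2).shape, dtype=np.int64)
        for t in range(self.p - 1, 0, -1):
            mask = (out == 0) & self.boundaries[t - 1].contains(u1, u2)
            out[mask] = t
        return int(out[0]) if scalar else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "p": self.p,
                "orientation": self.orientation.to_list(),
                "boundaries": [
                    [[c1, c2] for c1, c2 in b.corners] for b in self.boundaries
                ],
                "training_error": self.training_error,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StaircaseModel":
        d = json.loads(text)
        return cls(
            p=d["p"],
            orientation=Orientation(*d["orientation"]),
            boundaries=tuple(
                UpperSetBoundary(tuple((float(c1), float(c2)) for c1, c2 in b))
                for b in d["boundaries"]
            ),
            training_error=float(d["training_error"]),
        )


def fit_staircase_arrays(x1, x2, y, p, orientation, w=None):
    """Array-based multiclass fit; returns (StaircaseModel, fitted labels).

    Recursively splits the class range [lo, hi] at t = lo + floor((hi-lo+1)/2)
    (so the top split is at floor(p/2)), solves the binary threshold problem
    on all points, and passes the parent assignment down as must-in/must-out
    constraints, which guarantees nested boundaries.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    w = np.ones(y.size) if w is None else np.asarray(w, dtype=float)
    if p < 2:
        raise PairstairError("p must be at least 2")
    if y.size == 0:
        raise PairstairError("at least one point is required")
    if (y < 0).any() or (y >= p).any():
        raise PairstairError(f"labels must lie in 0..{p - 1}")

    o1, o2 = orientation.apply(x1, x2)
    boundaries: list = [None] * (p - 1)
    errors = np.zeros(p - 1)
    assigned = np.zeros(y.size, dtype=np.int64)

    def rec(lo: int, hi: int, force: np.ndarray):
        if lo >= hi:
            return
        t = lo + (hi - lo + 1) // 2
        b = (y >= t).astype(np.int64)
        err, in_up = solve_binary(o1, o2, b, w, force)
        errors[t - 1] = err
        boundaries[t - 1] = UpperSetBoundary(corners_from_assignment(o1, o2, in_up))
        assigned[in_up] += 1
        f_lo = force.copy()
        f_lo[in_up] = 1
        f_hi = force.copy()
        f_hi[~in_up] = -1
        rec(lo, t - 1, f_lo)
        rec(t, hi, f_hi)

    rec(0, p - 1, np.zeros(y.size, dtype=np.int8))
    model = StaircaseModel(
        p=p,
        orientation=orientation,
        boundaries=tuple(boundaries),
        training_error=float(errors.sum()),
    )
    return model, assigned


def fit_multiclass_staircase(
    points: Sequence[LabeledPoint], p: int, orientation: Orientation
) -> StaircaseModel:
    """Globally L1-optimal monotone classifier into p ordered classes."""
    x1, x2, y, w = _points_to_arrays(points)
    model, _ = fit_staircase_arrays(x1, x2, y, p, orientation, w)
    return model


def fit_best_orientation(points: Sequence[LabeledPoint], p: int):
    """Fit all four orientations; return (orientation, model) with minimal
    training error, ties broken in the order (+,+), (+,-), (-,+), (-,-)."""
    x1, x2, y, w = _points_to_arrays(points)
    return fit_best_orientation_arrays(x1, x2, y, p, w)


def fit_best_orientation_arrays(x1, x2, y, p, w=None):
    best = None
    for orientation in ORIENTATIONS:
        model, _ = fit_staircase_arrays(x1, x2, y, p, orientation, w)
        if best is None or model.training_error < best[1].training_error:
            best = (orientation, model)
    return best
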