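"""Exact weighted-L1 binary upper-set solver on two oriented coordinates.

A monotone upper set in the plane restricted to a finite point set is fully
described by a nonincreasing threshold function over the distinct x values:
a point (x, y) is inside iff y >= g(x).  The solver runs a dynamic program
over x-columns with one state per candidate y-threshold, which is exact and
O(n^2) in the worst case.  Among all optimal upper sets it returns the
unique SMALLEST one (fewest points assigned inside); the set of optimal
solutions is a lattice closed under intersection, so this canonical choice
is well defined and its per-column thresholds are the columnwise maxima
over all optimal solutions.
"""

from __future__ import annotations

import numpy as np

from .errors import PairstairError

try:  # numba accelerates the DP by ~100x; the pure-python path is identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


@njit(cache=True)
def _solve_levels(xcol, ypos, cost_in, cost_out, m, K):  # pragma: no cover
    # Level l in [0, K] for a column means: points with ypos >= l are inside;
    # l == K means the column is entirely outside.  Levels are nonincreasing
    # from left to right (thresholds decrease as x grows).
    colcost = np.zeros((m, K + 1))
    n = xcol.size
    for i in range(n):
        j = xcol[i]
        p = ypos[i]
        for l in range(0, p + 1):
            colcost[j, l] += cost_in[i]
        for l in range(p + 1, K + 1):
            colcost[j, l] += cost_out[i]

    # Forward: F[j, l] = min cost of columns 0..j with level_j == l.
    F = np.empty((m, K + 1))
    for l in range(K + 1):
        F[0, l] = colcost[0, l]
    suf = np.empty(K + 1)
    for j in range(1, m):
        suf[K] = F[j - 1, K]
        for l in range(K - 1, -1, -1):
            suf[l] = min(suf[l + 1], F[j - 1, l])
        for l in range(K + 1):
            F[j, l] = colcost[j, l] + suf[l]
    opt = F[m - 1, 0]
    for l in range(1, K + 1):
        if F[m - 1, l] < opt:
            opt = F[m - 1, l]

    # Backward: C[j, l] = min cost of columns j..m-1 with level_j == l;
    # P[j, l] = min over l' <= l of C[j, l'].
    P = np.empty((m, K + 1))
    C = np.empty(K + 1)
    for l in range(K + 1):
        C[l] = colcost[m - 1, l]
    P[m - 1, 0] = C[0]
    for l in range(1, K + 1):
        P[m - 1, l] = min(P[m - 1, l - 1], C[l])
    for j in range(m - 2, -1, -1):
        for l in range(K + 1):
            C[l] = colcost[j, l] + P[j + 1, l]
        P[j, 0] = C[0]
        for l in range(1, K + 1):
            P[j, l] = min(P[j, l - 1], C[l])

    # Canonical smallest optimal set: per column, the largest level that is
    # part of some optimal solution (the lattice meet of all optima).
    tol = 1e-9 * (1.0 + abs(opt)) if np.isfinite(opt) else 0.0
    levels = np.empty(m, np.int64)
    for j in range(m):
        best = K
        for l in range(K, -1, -1):
            rest = 0.0 if j == m - 1 else P[j + 1, l]
            if F[j, l] + rest <= opt + tol:
                best = l
                break
        levels[j] = best
    return opt, levels


def solve_binary(o1, o2, labels, weights, force=None):
    """Minimize sum(w * |[point in U] - label|) over monotone upper sets U.

    Parameters
    ----------
    o1, o2 : float arrays, oriented coordinates (label nondecreasing in both).
    labels : 0/1 integer array.
    weights : nonnegative float array.
    force : optional int8 array; +1 = point must be inside U, -1 = must be
        outside, 0 = free.  Used to nest recursive multiclass fits.

    Returns
    -------
    (error, in_upper) : achieved total weighted error and a boolean mask of
    the points assigned to the smallest optimal upper set.
    """
    o1 = np.asarray(o1, dtype=np.float64)
    o2 = np.asarray(o2, dtype=np.float64)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=np.float64)
    n = o1.size
    if n == 0:
        raise PairstairError("binary upper-set fit requires at least one point")
    if not (np.isfinite(o1).all() and np.isfinite(o2).all()):
        raise PairstairError("coordinates must be finite")
    if (weights < 0).any():
        raise PairstairError("weights must be nonnegative")
    if not np.isin(labels, (0, 1)).all():
        raise PairstairError("binary fit labels must be 0 or 1")

    ux, xcol = np.unique(o1, return_inverse=True)
    uy, ypos = np.unique(o2, return_inverse=True)
    m, K = ux.size, uy.size

    cost_in = np.where(labels == 0, weights, 0.0)
    cost_out = np.where(labels == 1, weights, 0.0)
    if force is not None:
        force = np.asarray(force)
        cost_in[force == -1] = np.inf
        cost_out[force == 1] = np.inf

    opt, levels = _solve_levels(
        xcol.astype(np.int64), ypos.astype(np.int64), cost_in, cost_out, m, K
    )
    if not np.isfinite(opt):
        raise PairstairError("infeasible region constraints in binary fit")
    if (np.diff(levels) > 0).any():  # lattice meet must itself be monotone
        raise AssertionError("internal error: non-monotone optimal thresholds")
    in_upper = levels[xcol] <= ypos
    return float(opt), in_upper


def corners_from_assignment(o1, o2, in_upper):
    """Minimal elements (antichain corners) of the points assigned inside.

    Returns the whole-plane sentinel ((-inf, -inf),) when every point is
    inside, and () when none is.
    """
    if not in_upper.any():
        return ()
    if in_upper.all():
        return ((-np.inf, -np.inf),)
    xs = np.asarray(o1)[in_upper]
    ys = np.asarray(o2)[in_upper]
    order = np.lexsort((ys, xs))
    corners = []
    best_y = np.inf
    prev_x = None
    for i in order:
        x, y = float(xs[i]), float(ys[i])
        if prev_x is not None and x == prev_x:
            continue  # only the lowest point of each column can be minimal
        prev_x = x
        if y < best_y:
            corners.append((x, y))
            best_y = y
    return tuple(corners)
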