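"""Fused JIT kernels for pair screening.

These reproduce, bit for bit, what the reference route does for a gene
pair — fit all four orientations per fold, pick the best by training error
(ties in the canonical order), build corner antichains, predict held-out
samples — but in a single compiled call per pair, avoiding per-fit Python
overhead.  Exact equality with the reference implementation in
:mod:`pairstair.staircase` is asserted by the test suite.

Per-threshold binary problems are solved independently (no nesting
constraints): the smallest optimal upper sets are automatically nested
across thresholds because the minimizer set of each modular objective is a
lattice and the point costs are monotone in the threshold, so this is
equivalent to the constrained recursion.
"""

from __future__ import annotations

import numpy as np

from ._solver import _solve_levels, njit

# Orientation index -> signs, in the canonical tie-break order.
_SIGNS = ((1, 1), (1, -1), (-1, 1), (-1, -1))


@njit(cache=True)
def _ranks(v):  # pragma: no cover
    """Sorted unique values and the rank of each element."""
    order = np.argsort(v, kind="mergesort")
    u = np.empty(v.size)
    inv = np.empty(v.size, np.int64)
    k = -1
    prev = 0.0
    for idx in range(v.size):
        i = order[idx]
        if k < 0 or v[i] != prev:
            k += 1
            u[k] = v[i]
            prev = v[i]
        inv[i] = k
    return u[: k + 1], inv


@njit(cache=True)
def _fit_orient(xcol, ypos, y, w, m, K, p):  # pragma: no cover
    """Independent per-threshold fits; total error and level matrix."""
    n = y.size
    total = 0.0
    levels = np.empty((p - 1, m), np.int64)
    cost_in = np.empty(n)
    cost_out = np.empty(n)
    for t in range(1, p):
        for i in range(n):
            if y[i] >= t:
                cost_in[i] = 0.0
                cost_out[i] = w[i]
            else:
                cost_in[i] = w[i]
                cost_out[i] = 0.0
        opt, lv = _solve_levels(xcol, ypos, cost_in, cost_out, m, K)
        total += opt
        levels[t - 1] = lv
    return total, levels


@njit(cache=True)
def _predict_threshold(lv, xcol, ypos, ux, uy, m, K, u1, u2, out):  # pragma: no cover
    """Add 1 to out[q] for each test point inside this threshold's upper set.

    Membership follows the corner convention: corners sit at the coordinates
    of assigned training points; all-inside maps to the whole plane.
    """
    n = xcol.size
    # Per-column minimum assigned y-rank (K means no assigned point).
    colmin = np.full(m, K, np.int64)
    n_in = 0
    for i in range(n):
        if ypos[i] >= lv[xcol[i]]:
            n_in += 1
            if ypos[i] < colmin[xcol[i]]:
                colmin[xcol[i]] = ypos[i]
    if n_in == 0:
        return
    if n_in == n:  # whole plane
        for q in range(u1.size):
            out[q] += 1
        return
    # Corner antichain: ascending x, strictly decreasing y.
    cx = np.empty(m)
    cy = np.empty(m)
    nc = 0
    best = K  # skips empty columns (colmin == K sentinel)
    for j in range(m):
        if colmin[j] < best:
            cx[nc] = ux[j]
            cy[nc] = uy[colmin[j]]
            nc += 1
            best = colmin[j]
    for q in range(u1.size):
        # last corner with cx <= u1[q]
        lo, hi = 0, nc - 1
        pos = -1
        while lo <= hi:
            mid = (lo + hi) // 2
            if cx[mid] <= u1[q]:
                pos = mid
                lo = mid + 1
            else:
                hi = mid - 1
        if pos >= 0 and u2[q] >= cy[pos]:
            out[q] += 1


@njit(cache=True)
def _best_orientation(x1, x2, y, w, p):  # pragma: no cover
    """(total error, orientation index) minimizing the multiclass L1 fit."""
    best_err = np.inf
    best_oi = 0
    for oi in range(4):
        s1 = 1.0 if oi < 2 else -1.0
        s2 = 1.0 if oi % 2 == 0 else -1.0
        ux, xcol = _ranks(s1 * x1)
        uy, ypos = _ranks(s2 * x2)
        total, _ = _fit_orient(xcol, ypos, y, w, ux.size, uy.size, p)
        if total < best_err:
            best_err = total
            best_oi = oi
    return best_err, best_oi


@njit(cache=True)
def _cv_abs_error(x1, x2, y, folds, n_folds, p):  # pragma: no cover
    """Total |pred - y| over all held-out samples of a stratified CV."""
    n = y.size
    total = 0.0
    for f in range(n_folds):
        n_te = 0
        for i in range(n):
            if folds[i] == f:
                n_te += 1
        n_tr = n - n_te
        x1tr = np.empty(n_tr)
        x2tr = np.empty(n_tr)
        ytr = np.empty(n_tr, np.int64)
        x1te = np.empty(n_te)
        x2te = np.empty(n_te)
        yte = np.empty(n_te, np.int64)
        a = 0
        b = 0
        for i in range(n):
            if folds[i] == f:
                x1te[b] = x1[i]
                x2te[b] = x2[i]
                yte[b] = y[i]
                b += 1
            else:
                x1tr[a] = x1[i]
                x2tr[a] = x2[i]
                ytr[a] = y[i]
                a += 1
        w = np.ones(n_tr)
        _, oi = _best_orientation(x1tr, x2tr, ytr, w, p)
        s1 = 1.0 if oi < 2 else -1.0
        s2 = 1.0 if oi % 2 == 0 else -1.0
        ux, xcol = _ranks(s1 * x1tr)
        uy, ypos = _ranks(s2 * x2tr)
        _, levels = _fit_orient(xcol, ypos, ytr, w, ux.size, uy.size, p)
        pred = np.zeros(n_te, np.int64)
        for t in range(p - 1):
            _predict_threshold(
                levels[t], xcol, ypos, ux, uy, ux.size, uy.size,
                s1 * x1te, s2 * x2te, pred,
            )
        for q in range(n_te):
            total += abs(pred[q] - yte[q])
    return total


def pair_full_error(x1, x2, y, p):
    """Best-orientation full-data training error; returns (error, signs)."""
    err, oi = _best_orientation(
        np.ascontiguousarray(x1, dtype=np.float64),
        np.ascontiguousarray(x2, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.int64),
        np.ones(len(y)),
        p,
    )
    return float(err), _SIGNS[oi]


def pair_cv_error(x1, x2, y, folds, n_folds, p):
    """Total held-out absolute error for one pair under fixed folds."""
    return float(
        _cv_abs_error(
            np.ascontiguousarray(x1, dtype=np.float64),
            np.ascontiguousarray(x2, dtype=np.float64),
            np.ascontiguousarray(y, dtype=np.int64),
            np.ascontiguousarray(folds, dtype=np.int64),
            n_folds,
            p,
        )
    )
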