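"""Genome-wide gene-pair screening with lower-bound preselection.

Every candidate pair gets a full-data optimal fit (``mae_full``); pairs are
then visited in ascending ``mae_full`` order, computing the cross-validated
``mae_cv``, until the next pair's ``mae_full`` exceeds the running threshold
theta (the N-th smallest ``mae_cv`` among the greedy disjoint set of visited
pairs).  Because ``mae_full`` lower-bounds ``mae_cv``, no unvisited pair can
beat theta, so the returned top set {mae_cv <= theta} matches what
exhaustive cross-validation of all pairs would select.  Observed violations
of the bound are logged loudly and counted, never silently ignored.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datasets import OrdinalDataset
from .errors import BoundViolationWarning, PairstairError
from ._pairfit import pair_cv_error, pair_full_error
from .staircase import Orientation, fit_best_orientation_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical unordered gene pair (gene_a < gene_b lexicographically)."""

    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise PairstairError("a pair must contain two distinct genes")
        if self.gene_a > self.gene_b:
            raise PairstairError(
                "pair genes must be in lexicographic order; use PairKey.of()"
            )

    @classmethod
    def of(cls, g1: str, g2: str) -> "PairKey":
        return cls(min(g1, g2), max(g1, g2))

    @property
    def genes(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class PairScore:
    pair: PairKey
    mae_full: float
    orientation: Orientation
    mae_cv: Optional[float] = None
    selected: bool = False

    def cv_sort_key(self):
        cv = np.inf if self.mae_cv is None else self.mae_cv
        return (cv, self.pair)


@dataclass(frozen=True)
class ScreenConfig:
    n_folds: int = 5
    min_disjoint: int = 5
    seed: int = 0
    max_pairs: Optional[int] = None

    def __post_init__(self):
        if self.n_folds < 2:
            raise PairstairError("n_folds must be at least 2")
        if self.min_disjoint < 1:
            raise PairstairError("min_disjoint must be at least 1")


@dataclass
class ScreenResult:
    """Outcome of a preselection screen."""

    visited: List[PairScore]  # all pairs whose CV error was computed
    top: List[PairScore]  # the selected top set, ascending (mae_cv, pair)
    theta: Optional[float]
    n_pairs_total: int
    n_bound_violations: int

    def top_pairs(self) -> List[PairKey]:
        return [s.pair for s in self.top]


def stratified_folds(ds: OrdinalDataset, n_folds: int, seed: int) -> np.ndarray:
    """Per-sample fold ids, stratified by class.

    Within each class, samples are ordered by id and dealt round-robin after
    a seeded shuffle, so the assignment is invariant to sample order.
    Classes are processed in ascending index order.
    """
    counts = np.bincount(ds.labels, minlength=ds.p)
    small = np.flatnonzero(counts < n_folds)
    if small.size:
        raise PairstairError(
            f"class {ds.class_names[small[0]]!r} has {counts[small[0]]} samples, "
            f"fewer than n_folds={n_folds}"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(ds.n_samples, dtype=np.int64)
    for c in range(ds.p):
        idx = np.flatnonzero(ds.labels == c)
        idx = idx[np.argsort([ds.samples[i] for i in idx], kind="stable")]
        perm = rng.permutation(idx.size)
        folds[idx[perm]] = np.arange(idx.size) % n_folds
    return folds


def _pair_rows(ds: OrdinalDataset, pair: PairKey):
    return ds.expr(pair.gene_a), ds.expr(pair.gene_b)


def mae_full(ds: OrdinalDataset, pair: PairKey) -> Tuple[float, Orientation]:
    """Per-sample MAE of the L1-optimal fit on all samples, best orientation."""
    x1, x2 = _pair_rows(ds, pair)
    err, (s1, s2) = pair_full_error(x1, x2, ds.labels, ds.p)
    return err / ds.n_samples, Orientation(s1, s2)


def mae_cv(
    ds: OrdinalDataset,
    pair: PairKey,
    config: ScreenConfig,
    folds: Optional[np.ndarray] = None,
) -> float:
    """Held-out MAE under stratified k-fold CV (orientation re-selected per fold)."""
    x1, x2 = _pair_rows(ds, pair)
    if folds is None:
        folds = stratified_folds(ds, config.n_folds, config.seed)
    return pair_cv_error(x1, x2, ds.labels, folds, config.n_folds, ds.p) / ds.n_samples


def mae_cv_reference(
    ds: OrdinalDataset,
    pair: PairKey,
    config: ScreenConfig,
    folds: Optional[np.ndarray] = None,
) -> float:
    """Plain-Python CV loop over the reference fit; oracle for mae_cv."""
    x1, x2 = _pair_rows(ds, pair)
    if folds is None:
        folds = stratified_folds(ds, config.n_folds, config.seed)
    total = 0.0
    for f in range(config.n_folds):
        test = folds == f
        train = ~test
        _, model = fit_best_orientation_arrays(
            x1[train], x2[train], ds.labels[train], ds.p
        )
        pred = model.predict(x1[test], x2[test])
        total += float(np.abs(pred - ds.labels[test]).sum())
    return total / ds.n_samples


def select_disjoint(pairs: Sequence[PairScore], m: int) -> List[PairScore]:
    """Greedy gene-disjoint selection by ascending (mae_cv, pair)."""
    if m < 1:
        raise PairstairError("m must be at least 1")
    chosen: List[PairScore] = []
    used: set = set()
    for score in sorted(pairs, key=PairScore.cv_sort_key):
        if len(chosen) == m:
            break
        a, b = score.pair.genes
        if a in used or b in used:
            continue
        chosen.append(score)
        used.update((a, b))
    return chosen


def all_pairs(genes: Sequence[str], max_pairs: Optional[int] = None) -> List[PairKey]:
    keys = sorted(PairKey.of(a, b) for a, b in itertools.combinations(genes, 2))
    return keys if max_pairs is None else keys[:max_pairs]


def preselect_top_pairs(ds: OrdinalDataset, config: ScreenConfig) -> ScreenResult:
    """Screen all gene pairs, pruning CV work via the mae_full lower bound."""
    if ds.n_genes < 2:
        raise PairstairError("screening needs at least two genes")
    if ds.n_genes < 2 * config.min_disjoint:
        raise PairstairError(
            f"{ds.n_genes} genes cannot yield {config.min_disjoint} disjoint pairs"
        )
    folds = stratified_folds(ds, config.n_folds, config.seed)
    candidates = all_pairs(ds.genes, config.max_pairs)

    scored = []
    for pair in candidates:
        full, orientation = mae_full(ds, pair)
        scored.append(PairScore(pair=pair, mae_full=full, orientation=orientation))
    scored.sort(key=lambda s: (s.mae_full, s.pair))

    visited: List[PairScore] = []
    theta: Optional[float] = None
    n_violations = 0
    for score in scored:
        if theta is not None and score.mae_full > theta:
            break  # the bound certifies no remaining pair can reach theta
        cv = mae_cv(ds, score.pair, config, folds)
        if score.mae_full > cv + 1e-12:
            n_violations += 1
            msg = (
                f"bound violation: pair {score.pair.gene_a}-{score.pair.gene_b} "
                f"has mae_full={score.mae_full:.6f} > mae_cv={cv:.6f}"
            )
            logger.warning(msg)
            warnings.warn(msg, BoundViolationWarning, stacklevel=2)
        visited.append(replace(score, mae_cv=cv))
        greedy = select_disjoint(visited, config.min_disjoint)
        if len(greedy) >= config.min_disjoint:
            theta = greedy[-1].mae_cv
    if theta is None:
        warnings.warn(
            "screen exhausted candidates before finding the requested number "
            "of disjoint pairs; returning all visited pairs"
        )
        top = sorted(visited, key=PairScore.cv_sort_key)
    else:
        top = sorted(
            (s for s in visited if s.mae_cv <= theta), key=PairScore.cv_sort_key
        )
    top = [replace(s, selected=True) for s in top]
    selected_keys = {s.pair for s in top}
    visited = [
        replace(s, selected=s.pair in selected_keys)
        for s in sorted(visited, key=PairScore.cv_sort_key)
    ]
    return ScreenResult(
        visited=visited,
        top=top,
        theta=theta,
        n_pairs_total=len(candidates),
        n_bound_violations=n_violations,
    )


def write_screen_tsv(result: ScreenResult, path):
    """Screen report: one row per visited pair, ascending (mae_cv, pair)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "gene_a\tgene_b\torientation_s1\torientation_s2\t"
            "mae_full\tmae_cv\tselected_flag\n"
        )
        for s in result.visited:
            fh.write(
                f"{s.pair.gene_a}\t{s.pair.gene_b}\t{s.orientation.s1}\t"
                f"{s.orientation.s2}\t{s.mae_full:.6f}\t{s.mae_cv:.6f}\t"
                f"{int(s.selected)}\n"
            )


def read_screen_tsv(path) -> List[PairScore]:
    scores = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_a\t"):
            raise PairstairError(f"{path}: not a screen TSV")
        for line in fh:
            ga, gb, s1, s2, full, cv, sel = line.rstrip("\n").split("\t")
            scores.append(
                PairScore(
                    pair=PairKey(ga, gb),
                    mae_full=float(full),
                    orientation=Orientation(int(s1), int(s2)),
                    mae_cv=float(cv),
                    selected=bool(int(sel)),
                )
            )
    return scores
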