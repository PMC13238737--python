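"""Resampling-based validation: training bootstrap, permutation and
randomization tests.

All procedures are reproducible from (seed, counts).  Permutation-style
p-values use the add-one estimator and therefore never equal zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datasets import OrdinalDataset
from .errors import PairstairError
from .metrics import METRICS, metric_report
from .screening import PairKey, ScreenConfig, mae_cv

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100  # per-resample cap when a class keeps vanishing


@dataclass(frozen=True)
class ResampleConfig:
    n_boot: int = 1000
    n_perm: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_boot < 1 or self.n_perm < 1:
            raise PairstairError("resample counts must be at least 1")
        if not 0.0 < self.ci_level < 1.0:
            raise PairstairError("ci_level must lie strictly between 0 and 1")


@dataclass
class BootstrapResult:
    summary: Dict[str, Tuple[float, float, float]]  # metric -> (median, lo, hi)
    per_resample: Dict[str, np.ndarray]
    n_failed: int
    n_redraws: int

    def write_tsv(self, path):
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("metric\tmedian\tci_low\tci_high\tn_failed\n")
            for name, (med, lo, hi) in self.summary.items():
                fh.write(f"{name}\t{med:.6f}\t{lo:.6f}\t{hi:.6f}\t{self.n_failed}\n")


Pipeline = Callable[[OrdinalDataset, OrdinalDataset], np.ndarray]


def bootstrap_evaluate(
    train: OrdinalDataset,
    test: OrdinalDataset,
    pipeline: Pipeline,
    config: ResampleConfig = ResampleConfig(),
) -> BootstrapResult:
    """Training-bootstrap uncertainty for a fit-and-predict pipeline.

    ``pipeline(train_resample, test)`` must return predicted labels for the
    fixed test set.  Each of ``n_boot`` resamples draws training rows with
    replacement (same size); resamples that lose a class entirely are
    redrawn (logged, capped at 100 attempts).  Returns the median and the
    central ``ci_level`` percentile interval per metric.
    """
    if set(train.samples) & set(test.samples):
        raise PairstairError("train and test sets must be disjoint")
    rng = np.random.default_rng(config.seed)
    n = train.n_samples
    collected: Dict[str, List[float]] = {name: [] for name in METRICS}
    n_failed = 0
    n_redraws = 0
    for _ in range(config.n_boot):
        idx = None
        for _attempt in range(_MAX_REDRAWS):
            cand = rng.integers(0, n, size=n)
            if np.bincount(train.labels[cand], minlength=train.p).min() > 0:
                idx = cand
                break
            n_redraws += 1
        if idx is None:
            n_failed += 1
            logger.warning("resample skipped: class vanished %d times", _MAX_REDRAWS)
            continue
        resample = train.take_samples(idx, dedupe_ids=True)
        try:
            y_pred = np.asarray(pipeline(resample, test))
        except Exception as exc:  # noqa: BLE001 - pipeline failures are data
            n_failed += 1
            logger.warning("pipeline failed on a resample: %s", exc)
            continue
        report = metric_report(test.labels, y_pred, p=test.p)
        for name, value in report["metrics"].items():
            collected[name].append(value)
    alpha = (1.0 - config.ci_level) / 2.0
    summary = {}
    per_resample = {}
    for name, vals in collected.items():
        arr = np.asarray(vals, dtype=float)
        per_resample[name] = arr
        if arr.size == 0:
            summary[name] = (np.nan, np.nan, np.nan)
        else:
            summary[name] = (
                float(np.quantile(arr, 0.5)),
                float(np.quantile(arr, alpha)),
                float(np.quantile(arr, 1.0 - alpha)),
            )
    if n_redraws:
        logger.info("redrew %d degenerate bootstrap resamples", n_redraws)
    return BootstrapResult(summary, per_resample, n_failed, n_redraws)


def permutation_mae_test(
    ds: OrdinalDataset,
    pair: PairKey,
    config: ResampleConfig = ResampleConfig(),
    n_folds: int = 5,
) -> float:
    """One-sided permutation p-value for a pair's cross-validated MAE.

    The null recomputes mae_cv after permuting the labels (expression
    untouched); p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    screen_cfg = ScreenConfig(n_folds=n_folds, min_disjoint=1, seed=config.seed)
    observed = mae_cv(ds, pair, screen_cfg)
    rng = np.random.default_rng(config.seed)
    hits = 0
    for _ in range(config.n_perm):
        permuted = OrdinalDataset(
            genes=list(ds.genes),
            samples=list(ds.samples),
            values=ds.values,
            labels=rng.permutation(ds.labels),
            class_names=list(ds.class_names),
        )
        if mae_cv(permuted, pair, screen_cfg) <= observed:
            hits += 1
    return (1 + hits) / (config.n_perm + 1)


def overlap_randomization_test(
    set_a: Sequence[str],
    set_b: Sequence[str],
    shared_universe: Sequence[str],
    config: ResampleConfig = ResampleConfig(),
    randomize: str = "both",
) -> float:
    """One-sided (enrichment) randomization test for gene-set overlap.

    The null redraws ``set_a`` and ``set_b`` (or only one of them, with
    ``randomize`` in {'a', 'b'}) as uniform same-size subsets of the shared
    universe; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    universe = list(dict.fromkeys(shared_universe))
    uset = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= uset or not b <= uset:
        raise PairstairError("both gene sets must lie within the shared universe")
    if randomize not in ("both", "a", "b"):
        raise PairstairError("randomize must be 'both', 'a' or 'b'")
    observed = len(a & b)
    rng = np.random.default_rng(config.seed)
    arr = np.asarray(universe)
    hits = 0
    for _ in range(config.n_perm):
        ra = (
            set(rng.choice(arr, size=len(a), replace=False))
            if randomize in ("both", "a")
            else a
        )
        rb = (
            set(rng.choice(arr, size=len(b), replace=False))
            if randomize in ("both", "b")
            else b
        )
        if len(ra & rb) >= observed:
            hits += 1
    return (1 + hits) / (config.n_perm + 1)
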