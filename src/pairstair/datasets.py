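"""Expression-matrix datasets with ordinal labels: IO, MAD filtering, splits.

Expression files are TSV/CSV with genes as rows (first column gene id,
header row of sample ids).  Label files are TSV with columns
``sample_id`` and ``class_name`` plus a directive line declaring the class
order from worst to best clinical outcome::

    #order: short,intermediate,long

Class index 0 is always the worst outcome.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import PairstairError

logger = logging.getLogger(__name__)


@dataclass
class OrdinalDataset:
    """Genes x samples expression matrix plus per-sample ordinal labels."""

    genes: List[str]
    samples: List[str]
    values: np.ndarray
    labels: np.ndarray
    class_names: List[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise PairstairError("values must be a genes x samples matrix")
        if self.labels.shape != (len(self.samples),):
            raise PairstairError("one label per sample is required")
        if len(set(self.genes)) != len(self.genes):
            raise PairstairError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise PairstairError("duplicate sample identifiers")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise PairstairError(
                f"non-finite expression value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        if (self.labels < 0).any() or (self.labels >= self.p).any():
            raise PairstairError("labels out of range for declared classes")
        present = np.bincount(self.labels, minlength=self.p)
        if (present == 0).any():
            missing = [self.class_names[i] for i in np.flatnonzero(present == 0)]
            warnings.warn(f"classes with no samples: {missing}", stacklevel=2)

    @property
    def p(self) -> int:
        return len(self.class_names)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def expr(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise PairstairError(f"unknown gene {gene!r}") from None

    def take_samples(self, indices, dedupe_ids: bool = False) -> "OrdinalDataset":
        indices = np.asarray(indices, dtype=np.int64)
        samples = [self.samples[i] for i in indices]
        if dedupe_ids:
            seen: dict = {}
            renamed = []
            for s in samples:
                k = seen.get(s, 0)
                seen[s] = k + 1
                renamed.append(s if k == 0 else f"{s}.{k}")
            samples = renamed
        return OrdinalDataset(
            genes=list(self.genes),
            samples=samples,
            values=self.values[:, indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
        )

    def take_genes(self, genes: Sequence[str]) -> "OrdinalDataset":
        idx = [self.genes.index(g) for g in genes]
        return OrdinalDataset(
            genes=list(genes),
            samples=list(self.samples),
            values=self.values[idx, :],
            labels=self.labels.copy(),
            class_names=list(self.class_names),
        )


def _read_table(path, what: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        return pd.read_csv(path, sep=sep, index_col=0, comment=None)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise PairstairError(f"cannot parse {what} file {path}: {exc}") from exc


def read_labels(path) -> Tuple[pd.Series, List[str]]:
    """Read a label file; returns (sample -> class name, class order)."""
    order = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#order:"):
                order = [c.strip() for c in line[len("#order:"):].split(",")]
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PairstairError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            rows.append((lineno, parts[0], parts[1]))
    if order is None:
        raise PairstairError(f"{path}: missing '#order: worst,...,best' directive")
    if len(order) < 2 or len(set(order)) != len(order):
        raise PairstairError(f"{path}: class order must list >= 2 distinct names")
    if rows and rows[0][1:] == ("sample_id", "class_name"):
        rows = rows[1:]
    ids, names = [], []
    for lineno, sid, cname in rows:
        if cname not in order:
            raise PairstairError(
                f"{path}:{lineno}: unknown class name {cname!r} "
                f"(declared order: {order})"
            )
        ids.append(sid)
        names.append(cname)
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise PairstairError(f"{path}: duplicate sample ids {dup}")
    return pd.Series(names, index=ids), order


def read_dataset(expr_path, labels_path, transpose: bool = False) -> OrdinalDataset:
    """Load expression + labels; samples are aligned by id (intersection)."""
    expr = _read_table(expr_path, "expression")
    if transpose:
        expr = expr.T
    if expr.index.has_duplicates:
        dup = sorted(expr.index[expr.index.duplicated()].unique())
        raise PairstairError(f"{expr_path}: duplicate gene ids {dup}")
    if expr.columns.has_duplicates:
        dup = sorted(expr.columns[expr.columns.duplicated()].unique())
        raise PairstairError(f"{expr_path}: duplicate sample ids {dup}")
    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        bad = coerced.isna() & expr[col].notna()
        if bad.any():
            gene = expr.index[bad][0]
            raise PairstairError(
                f"{expr_path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        expr[col] = coerced

    label_series, order = read_labels(labels_path)
    keep = [s for s in expr.columns if s in label_series.index]
    n_dropped = (len(expr.columns) - len(keep)) + (len(label_series) - len(keep))
    if n_dropped:
        logger.info("dropped %d samples absent from one of the files", n_dropped)
    if not keep:
        raise PairstairError("no samples shared between expression and labels")
    expr = expr[keep]
    rank = {name: i for i, name in enumerate(order)}
    labels = np.array([rank[label_series[s]] for s in keep], dtype=np.int64)
    return OrdinalDataset(
        genes=[str(g) for g in expr.index],
        samples=[str(s) for s in keep],
        values=expr.to_numpy(dtype=float),
        labels=labels,
        class_names=list(order),
    )


def write_dataset(ds: OrdinalDataset, expr_path, labels_path, float_fmt: str = "%.6g"):
    """Write the standard TSV pair (lossless at 6 significant digits)."""
    with open(expr_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(ds.samples) + "\n")
        for g, row in zip(ds.genes, ds.values):
            fh.write(g + "\t" + "\t".join(float_fmt % v for v in row) + "\n")
    with open(labels_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#order: " + ",".join(ds.class_names) + "\n")
        fh.write("sample_id\tclass_name\n")
        for s, lab in zip(ds.samples, ds.labels):
            fh.write(f"{s}\t{ds.class_names[lab]}\n")


def mad_filter(
    ds: OrdinalDataset,
    keep_top: Optional[int] = None,
    min_mad: Optional[float] = None,
) -> OrdinalDataset:
    """Keep high-variability genes by median absolute deviation.

    Exactly one of ``keep_top`` (top-k genes by MAD, ties by gene id) or
    ``min_mad`` (MAD >= threshold) must be given.  The sample axis is
    untouched and surviving genes keep their original order.
    """
    if (keep_top is None) == (min_mad is None):
        raise PairstairError("give exactly one of keep_top or min_mad")
    med = np.median(ds.values, axis=1, keepdims=True)
    mads = np.median(np.abs(ds.values - med), axis=1)
    if keep_top is not None:
        if keep_top > ds.n_genes:
            warnings.warn(
                f"keep_top={keep_top} exceeds gene count {ds.n_genes}; keeping all"
            )
            keep_top = ds.n_genes
        ranked = sorted(range(ds.n_genes), key=lambda i: (-mads[i], ds.genes[i]))
        chosen = set(ranked[:keep_top])
        keep = [g for i, g in enumerate(ds.genes) if i in chosen]
    else:
        keep = [g for i, g in enumerate(ds.genes) if mads[i] >= min_mad]
        if not keep:
            raise PairstairError(f"no gene has MAD >= {min_mad}")
    return ds.take_genes(keep)


def gene_mad(values: np.ndarray) -> np.ndarray:
    """Row-wise median absolute deviation (no consistency scaling)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def round_half_away(x: float) -> int:
    """Nearest integer, halves away from zero (matches reported split counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_class_counts(class_sizes: Sequence[int], train_frac: float) -> List[int]:
    """Per-class training counts under the stratified split rounding rule."""
    if not 0.0 < train_frac < 1.0:
        raise PairstairError("train_frac must lie strictly between 0 and 1")
    return [round_half_away(train_frac * n) for n in class_sizes]


def stratified_split(
    ds: OrdinalDataset, train_frac: float = 0.8, seed: int = 0
) -> Tuple[OrdinalDataset, OrdinalDataset]:
    """Seeded stratified partition preserving class proportions.

    Per class, the training count is the nearest integer (half away from
    zero) to ``train_frac * class_size``; membership is a seeded shuffle of
    the class's samples ordered by id, so the split is invariant to sample
    order in the input.
    """
    if not 0.0 < train_frac < 1.0:
        raise PairstairError("train_frac must lie strictly between 0 and 1")
    counts = np.bincount(ds.labels, minlength=ds.p)
    small = np.flatnonzero(counts < 2)
    if small.size:
        raise PairstairError(
            f"class {ds.class_names[small[0]]!r} has fewer than 2 samples"
        )
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(ds.n_samples, dtype=bool)
    for c in range(ds.p):
        idx = np.flatnonzero(ds.labels == c)
        idx = idx[np.argsort([ds.samples[i] for i in idx], kind="stable")]
        perm = rng.permutation(idx.size)
        n_train = round_half_away(train_frac * idx.size)
        train_mask[idx[perm[:n_train]]] = True
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(~train_mask)
    return ds.take_samples(train_idx), ds.take_samples(test_idx)
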