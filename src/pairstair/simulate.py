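"""Synthetic expression datasets with planted monotone gene pairs.

Each planted pair carries an orientation (s1, s2); a per-sample latent score
s = s1*x1 + s2*x2 falls strictly inside the unit bin of the sample's
pre-noise label, so at flip_rate 0 the label is exactly realizable by a
monotone staircase on the pair (zero optimal L1 error by construction).
Gaussian variation is injected along the score-preserving direction, which
keeps that guarantee intact.  All other genes are label-independent noise.

Every component draws from its own seed sub-stream, so changing n_genes or
adding planted pairs never perturbs previously generated columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datasets import OrdinalDataset
from .errors import PairstairError
from .screening import PairKey

_EDGE_MARGIN = 1e-3  # keep scores away from bin edges (float safety)


@dataclass(frozen=True)
class PlantedPair:
    pair: PairKey
    s1: int
    s2: int


@dataclass(frozen=True)
class SynthConfig:
    n_samples: int
    n_genes: int
    p: int = 3
    n_planted_pairs: int = 1
    flip_rate: float = 0.0
    orientations: Optional[Tuple[Tuple[int, int], ...]] = None
    class_weights: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.p < 2:
            raise PairstairError("need n_samples >= 1 and p >= 2")
        if self.n_genes < 2 * self.n_planted_pairs:
            raise PairstairError("n_genes must be >= 2 * n_planted_pairs")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise PairstairError("flip_rate must lie in [0, 1]")
        if self.orientations is not None:
            if len(self.orientations) != self.n_planted_pairs:
                raise PairstairError("one orientation per planted pair required")
            for s1, s2 in self.orientations:
                if s1 not in (1, -1) or s2 not in (1, -1):
                    raise PairstairError("orientation signs must be +1 or -1")
        if self.class_weights is not None:
            wsum = float(np.sum(self.class_weights))
            if len(self.class_weights) != self.p or abs(wsum - 1.0) > 1e-9:
                raise PairstairError("class_weights must have length p and sum to 1")
            if (np.asarray(self.class_weights) < 0).any():
                raise PairstairError("class_weights must be nonnegative")

    def weights(self) -> np.ndarray:
        if self.class_weights is None:
            return np.full(self.p, 1.0 / self.p)
        return np.asarray(self.class_weights, dtype=float)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed,) + key))


def gene_name(index: int) -> str:
    return f"g{index:05d}"


def generate(config: SynthConfig) -> Tuple[OrdinalDataset, List[PlantedPair]]:
    """Generate (dataset, ground truth list of planted pairs)."""
    n, p = config.n_samples, config.p
    base_labels = _stream(config.seed, 0).choice(p, size=n, p=config.weights())

    orientations = config.orientations or ((1, 1),) * config.n_planted_pairs
    values = np.empty((config.n_genes, n))
    truth: List[PlantedPair] = []
    for i, (s1, s2) in enumerate(orientations):
        rng = _stream(config.seed, 1, i)
        score = base_labels + rng.uniform(_EDGE_MARGIN, 1.0 - _EDGE_MARGIN, size=n)
        o1 = rng.normal(0.0, 1.0, size=n)
        o2 = score - o1  # o1 + o2 == score exactly: label stays monotone
        ga, gb = gene_name(2 * i), gene_name(2 * i + 1)
        values[2 * i] = s1 * o1
        values[2 * i + 1] = s2 * o2
        truth.append(PlantedPair(PairKey(ga, gb), s1, s2))

    for g in range(2 * config.n_planted_pairs, config.n_genes):
        values[g] = _stream(config.seed, 2, g).normal(0.0, 1.0, size=n)

    labels = base_labels.copy()
    if config.flip_rate > 0:
        rng = _stream(config.seed, 3)
        flip = rng.uniform(size=n) < config.flip_rate
        labels[flip] = rng.integers(0, p, size=int(flip.sum()))

    ds = OrdinalDataset(
        genes=[gene_name(g) for g in range(config.n_genes)],
        samples=[f"s{i:05d}" for i in range(n)],
        values=values,
        labels=labels,
        class_names=[f"c{k}" for k in range(p)],
    )
    return ds, truth


def write_ground_truth(truth: Sequence[PlantedPair], path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\ts1\ts2\n")
        for t in truth:
            fh.write(f"{t.pair.gene_a}\t{t.pair.gene_b}\t{t.s1}\t{t.s2}\n")
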