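"""Voting ensembles of disjoint gene-pair staircase classifiers.

Each member votes a discrete ordinal label; the ensemble returns the label
with the highest count and resolves ties toward the worst outcome (the
smallest label under the 0 = worst convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datasets import OrdinalDataset
from .errors import PairstairError
from .screening import (
    PairKey,
    PairScore,
    ScreenConfig,
    select_disjoint,
    stratified_folds,
)
from .staircase import StaircaseModel, fit_best_orientation_arrays

DEFAULT_SIZES = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class EnsembleModel:
    members: Tuple[Tuple[PairKey, StaircaseModel], ...]
    p: int

    def __post_init__(self):
        genes = [g for pair, _ in self.members for g in pair.genes]
        if len(set(genes)) != len(genes):
            raise PairstairError("ensemble members must be gene-disjoint")
        for _, model in self.members:
            if model.p != self.p:
                raise PairstairError("all members must share the class count")

    @property
    def genes(self) -> List[str]:
        return [g for pair, _ in self.members for g in pair.genes]

    def to_json(self) -> str:
        return json.dumps(
            {
                "p": self.p,
                "members": [
                    {
                        "gene_a": pair.gene_a,
                        "gene_b": pair.gene_b,
                        "model": json.loads(model.to_json()),
                    }
                    for pair, model in self.members
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        d = json.loads(text)
        return cls(
            members=tuple(
                (
                    PairKey(m["gene_a"], m["gene_b"]),
                    StaircaseModel.from_json(json.dumps(m["model"])),
                )
                for m in d["members"]
            ),
            p=d["p"],
        )


def majority_vote(votes: Sequence[int]) -> int:
    """Label with the highest count; ties go to the smallest (worst) label."""
    if len(votes) == 0:
        raise PairstairError("cannot vote with zero members")
    counts: Dict[int, int] = {}
    for v in votes:
        counts[int(v)] = counts.get(int(v), 0) + 1
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def predict_ensemble(model: EnsembleModel, x: Mapping[str, float]) -> int:
    """Predict one sample given expression values for all member genes."""
    votes = []
    for pair, member in model.members:
        for g in pair.genes:
            if g not in x:
                raise PairstairError(f"missing expression value for gene {g!r}")
        votes.append(member.predict(x[pair.gene_a], x[pair.gene_b]))
    return majority_vote(votes)


def predict_ensemble_dataset(model: EnsembleModel, ds: OrdinalDataset) -> np.ndarray:
    """Vectorized ensemble prediction for every sample of a dataset."""
    votes = np.empty((len(model.members), ds.n_samples), dtype=np.int64)
    for i, (pair, member) in enumerate(model.members):
        votes[i] = member.predict(ds.expr(pair.gene_a), ds.expr(pair.gene_b))
    return np.array([majority_vote(votes[:, j]) for j in range(ds.n_samples)])


def build_ensemble(
    ds: OrdinalDataset, top_pairs: Sequence[PairScore], m: int
) -> EnsembleModel:
    """Refit the m best disjoint pairs on the full dataset."""
    chosen = select_disjoint(top_pairs, m)
    if len(chosen) < m:
        raise PairstairError(
            f"only {len(chosen)} disjoint pairs available, {m} requested"
        )
    members = []
    for score in chosen:
        x1, x2 = ds.expr(score.pair.gene_a), ds.expr(score.pair.gene_b)
        _, model = fit_best_orientation_arrays(x1, x2, ds.labels, ds.p)
        members.append((score.pair, model))
    return EnsembleModel(members=tuple(members), p=ds.p)


def choose_ensemble_size(
    ds: OrdinalDataset,
    top_pairs: Sequence[PairScore],
    candidate_sizes: Optional[Sequence[int]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> int:
    """Pick the member count minimizing CV MAE of the voted prediction.

    Member pairs are fixed by greedy disjoint selection from ``top_pairs``
    but refit within each training fold; ties prefer the smallest size.
    """
    sizes = sorted(candidate_sizes or DEFAULT_SIZES)
    achievable = [m for m in sizes if len(select_disjoint(top_pairs, m)) == m]
    if not achievable:
        raise PairstairError("no candidate ensemble size is achievable")
    folds = stratified_folds(ds, config.n_folds, config.seed)
    best_m, best_mae = None, np.inf
    for m in achievable:
        chosen = select_disjoint(top_pairs, m)
        total = 0.0
        for f in range(config.n_folds):
            test = folds == f
            train = ~test
            votes = np.empty((m, int(test.sum())), dtype=np.int64)
            for i, score in enumerate(chosen):
                x1 = ds.expr(score.pair.gene_a)
                x2 = ds.expr(score.pair.gene_b)
                _, model = fit_best_orientation_arrays(
                    x1[train], x2[train], ds.labels[train], ds.p
                )
                votes[i] = model.predict(x1[test], x2[test])
            pred = np.array([majority_vote(votes[:, j]) for j in range(votes.shape[1])])
            total += float(np.abs(pred - ds.labels[test]).sum())
        cv_mae = total / ds.n_samples
        if cv_mae < best_mae:
            best_m, best_mae = m, cv_mae
    return best_m


def write_predictions_tsv(sample_ids: Sequence[str], predictions, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tpredicted_class\n")
        for sid, pred in zip(sample_ids, predictions):
            fh.write(f"{sid}\t{int(pred)}\n")


def read_predictions_tsv(path) -> Tuple[List[str], np.ndarray]:
    ids, preds = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("sample_id\t"):
            raise PairstairError(f"{path}: not a predictions TSV")
        for line in fh:
            sid, pred = line.rstrip("\n").split("\t")
            ids.append(sid)
            preds.append(int(pred))
    return ids, np.asarray(preds, dtype=np.int64)
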