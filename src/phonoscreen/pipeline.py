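"""The two-step evaluation protocol: balanced CV then unbalanced held-out.

Step 1 draws a balanced subset (default 1500 recordings per class), runs
10-fold cross-validation over multiple iterations with feature selection on
the training folds only, and traces balanced accuracy as a function of the
number of top-ranked features presented to the classifier.  Step 2 trains
the chosen configuration on the full balanced set and evaluates exactly
once on the untouched, unbalanced remainder.  A provenance log records
every recording id used on the training side so leakage is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import PhonoscreenError
from .model import EvalReport, evaluate, fit_model, tune_and_train
from .selection import FeatureRanking, vote

Ranker = Callable[[np.ndarray, np.ndarray], FeatureRanking]


@dataclass
class CohortDataset:
    """Feature matrix + labels + ids with participant bookkeeping."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    participant_ids: np.ndarray | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.ids = np.asarray(self.ids)
        if len(self.X) != len(self.y) or len(self.y) != len(self.ids):
            raise ValueError("X, y, ids must have equal length")

    def subset(self, idx: np.ndarray) -> "CohortDataset":
        return CohortDataset(
            X=self.X[idx], y=self.y[idx], ids=self.ids[idx],
            participant_ids=(self.participant_ids[idx]
                             if self.participant_ids is not None else None),
            feature_names=self.feature_names)


@dataclass
class SplitPlan:
    balanced_ids: np.ndarray
    heldout_ids: np.ndarray
    seed: int
    n_per_class: int

    def __post_init__(self) -> None:
        if set(self.balanced_ids) & set(self.heldout_ids):
            raise ValueError("balanced and held-out sets overlap")


@dataclass
class Provenance:
    """Ids that have entered any selection/tuning/training call."""

    training_side_ids: set = field(default_factory=set)

    def record(self, ids: np.ndarray) -> None:
        self.training_side_ids.update(np.asarray(ids).tolist())

    def assert_disjoint(self, heldout_ids: np.ndarray) -> None:
        leak = self.training_side_ids & set(np.asarray(heldout_ids).tolist())
        if leak:
            raise PhonoscreenError(f"leakage: {len(leak)} held-out ids used "
                                   "on the training side")


@dataclass
class PerformanceCurve:
    k_grid: np.ndarray
    mean_ba: np.ndarray
    sd_ba: np.ndarray
    mean_sens: np.ndarray
    mean_spec: np.ndarray
    chosen_k: int


def make_split(dataset: CohortDataset, n_per_class: int = 1500,
               seed: int = 0) -> SplitPlan:
    """Uniformly sample a balanced subset per class; the rest is held out."""
    rng = np.random.default_rng(seed)
    chosen = []
    for c in (0, 1):
        idx = np.where(dataset.y == c)[0]
        if len(idx) < n_per_class:
            raise PhonoscreenError(
                f"class {c} has {len(idx)} < {n_per_class} recordings")
        chosen.append(rng.choice(idx, size=n_per_class, replace=False))
    bal = np.sort(np.concatenate(chosen))
    mask = np.zeros(len(dataset.y), dtype=bool)
    mask[bal] = True
    return SplitPlan(balanced_ids=dataset.ids[bal],
                     heldout_ids=dataset.ids[~mask],
                     seed=seed, n_per_class=n_per_class)


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.asarray(sorted(f)) for f in folds]


def run_cv(balanced: CohortDataset, ranker: Ranker, classifier_config,
           folds: int = 10, iterations: int = 100, k_max: int = 30,
           seed: int = 0, provenance: Provenance | None = None
           ) -> PerformanceCurve:
    """Cross-validated performance as a function of feature count.

    Per fold: features are ranked on the training fold only, then for each
    k in 1..k_max the classifier (fixed hyper-parameters from the config)
    is trained on the top-k features and scored on the test fold.
    chosen_k is the smallest k whose mean balanced accuracy lies within one
    SD of the maximum.
    """
    rng = np.random.default_rng(seed)
    k_grid = np.arange(1, k_max + 1)
    ba = np.zeros((iterations * folds, k_max))
    sens = np.zeros_like(ba)
    spec = np.zeros_like(ba)
    row = 0
    for _ in range(iterations):
        fold_idx = _stratified_folds(balanced.y, folds, rng)
        for f in range(folds):
            test_idx = fold_idx[f]
            train_idx = np.concatenate(
                [fold_idx[g] for g in range(folds) if g != f])
            if provenance is not None:
                provenance.record(balanced.ids[train_idx])
            ranking = ranker(balanced.X[train_idx], balanced.y[train_idx])
            for ki, k in enumerate(k_grid):
                cols = ranking.order[:k]
                m = fit_model(balanced.X[np.ix_(train_idx, cols)],
                              balanced.y[train_idx], classifier_config)
                rep = evaluate(m, balanced.X[np.ix_(test_idx, cols)],
                               balanced.y[test_idx])
                ba[row, ki] = rep.balanced_accuracy
                sens[row, ki] = rep.sensitivity
                spec[row, ki] = rep.specificity
            row += 1
    mean_ba = ba.mean(axis=0)
    sd_ba = ba.std(axis=0)
    best = int(np.argmax(mean_ba))
    within = np.where(mean_ba >= mean_ba[best] - sd_ba[best])[0]
    chosen_k = int(k_grid[within[0]])
    return PerformanceCurve(k_grid=k_grid, mean_ba=mean_ba, sd_ba=sd_ba,
                            mean_sens=sens.mean(axis=0),
                            mean_spec=spec.mean(axis=0), chosen_k=chosen_k)


def finalize_and_validate(balanced: CohortDataset, heldout: CohortDataset,
                          chosen_k: int, ranker: Ranker, classifier_config,
                          seed: int = 0, tune: bool = False,
                          provenance: Provenance | None = None) -> EvalReport:
    """Train the final model on the balanced set; evaluate once on held-out.

    Feature ranking (and optional hyper-parameter tuning) touch only the
    balanced set; the provenance audit refuses any overlap with held-out
    ids.
    """
    if provenance is None:
        provenance = Provenance()
    provenance.record(balanced.ids)
    provenance.assert_disjoint(heldout.ids)
    ranking = ranker(balanced.X, balanced.y)
    cols = ranking.order[:chosen_k]
    Xb = balanced.X[:, cols]
    if tune:
        m = tune_and_train(Xb, balanced.y, classifier_config, seed=seed)
    else:
        m = fit_model(Xb, balanced.y, classifier_config)
    return evaluate(m, heldout.X[:, cols], heldout.y)


def voted_ranker(base: Ranker, folds: int = 10, top_k: int = 30,
                 seed: int = 0) -> Ranker:
    """Wrap a ranker with within-training-set fold voting.

    The base ranker runs on each of ``folds`` training folds; the tallies'
    final order becomes the ranking (vote counts as scores).
    """

    def ranked(X: np.ndarray, y: np.ndarray) -> FeatureRanking:
        rng = np.random.default_rng(seed)
        fold_idx = _stratified_folds(np.asarray(y), folds, rng)
        rankings = []
        for f in range(folds):
            train_idx = np.concatenate(
                [fold_idx[g] for g in range(folds) if g != f])
            rankings.append(base(np.asarray(X)[train_idx],
                                 np.asarray(y)[train_idx]))
        tally = vote(rankings, top_k=top_k)
        return FeatureRanking(method=f"voted_{rankings[0].method}",
                              order=tally.final_order,
                              scores=tally.votes.astype(float))

    return ranked
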