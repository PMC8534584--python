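"""Feature-selection rankers and cross-validated vote aggregation.

Three complementary rankers — Gram-Schmidt orthogonalisation (forward
selection on residual correlation), ReliefF (k-nearest hit/miss margins)
and Simba (iterative hypothesis-margin weight learning) — each produce a
full feature ranking.  Rankings from repeated cross-validation runs are
aggregated by counting, per feature, how often it lands in a run's top-30
("voting"), which stabilises the final subset against fold-to-fold noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    method: str
    order: np.ndarray      # feature indices, best first
    scores: np.ndarray     # per-feature relevance (aligned to feature index)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        assert sorted(self.order.tolist()) == list(range(len(self.order)))
        assert np.all(np.isfinite(self.scores))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def gso_rank(X: np.ndarray, y: np.ndarray, k: int = 30) -> FeatureRanking:
    """Gram-Schmidt forward selection on squared label correlation.

    At each step the (orthogonalised) column with the largest squared
    correlation against the current label residual is selected, then its
    direction is projected out of the remaining columns and the residual.
    Unselected features follow the selected ones, ordered by final score.
    """
    Xs = _standardize(np.asarray(X, dtype=float))
    r = np.where(np.asarray(y) > 0, 1.0, -1.0)
    r = r - r.mean()
    n, p = Xs.shape
    if n <= k:
        raise ValueError("need more samples than selected features")
    remaining = list(range(p))
    selected: list[int] = []
    scores = np.zeros(p)
    Q = Xs.copy()
    for step in range(min(k, p)):
        norms = np.linalg.norm(Q[:, remaining], axis=0)
        if np.all(norms < 1e-10):
            logger.warning("gso: rank-deficient at step %d, stopping", step)
            break
        corr = np.zeros(len(remaining))
        for i, j in enumerate(remaining):
            if norms[i] >= 1e-10:
                corr[i] = (Q[:, j] @ r) ** 2 / (norms[i] ** 2)
        best = int(np.argmax(corr))
        j = remaining.pop(best)
        selected.append(j)
        scores[j] = corr[best] + (k - step)  # selection order dominates
        q = Q[:, j] / np.linalg.norm(Q[:, j])
        Q[:, remaining] -= np.outer(q, q @ Q[:, remaining])
        r = r - q * (q @ r)
    # rank the unselected by their final-step residual correlation
    for i, j in enumerate(remaining):
        nj = np.linalg.norm(Q[:, j])
        scores[j] = (Q[:, j] @ r) ** 2 / (nj**2) if nj > 1e-10 else 0.0
    order = np.asarray(selected + sorted(remaining,
                                         key=lambda j: -scores[j]))
    return FeatureRanking(method="gso", order=order, scores=scores)


def relief_rank(X: np.ndarray, y: np.ndarray,
                n_neighbors: int = 10) -> FeatureRanking:
    """ReliefF weights from k-nearest hits and misses (standardised space)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Xs = _standardize(X)
    n, p = Xs.shape
    rng_cols = X.max(axis=0) - X.min(axis=0)
    rng_cols[rng_cols == 0] = 1.0
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError("need at least 2 samples per class")
    k_eff = min(n_neighbors, min(int(np.sum(y == c)) for c in classes) - 1)
    if k_eff < n_neighbors:
        logger.warning("relief: reduced neighbourhood to %d", k_eff)

    d2 = np.sum(Xs**2, axis=1)
    D = d2[:, None] + d2[None, :] - 2.0 * (Xs @ Xs.T)
    np.fill_diagonal(D, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = np.where(y == y[i])[0]
        diff = np.where(y != y[i])[0]
        hits = same[np.argsort(D[i, same])[:k_eff]]
        misses = diff[np.argsort(D[i, diff])[:k_eff]]
        w += (np.abs(X[misses] - X[i]).mean(axis=0)
              - np.abs(X[hits] - X[i]).mean(axis=0)) / rng_cols
    w /= n
    order = np.argsort(-w, kind="stable")
    return FeatureRanking(method="relief", order=order, scores=w)


def simba_rank(X: np.ndarray, y: np.ndarray, n_passes: int = 5,
               seed: int | None = 0, learning_rate: float = 0.1
               ) -> FeatureRanking:
    """Simba: gradient ascent on the hypothesis margin with linear utility.

    Feature weights scale the metric in which nearest hit/miss are found;
    after the final pass features are ranked by w**2.
    """
    X = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, p = X.shape
    classes = np.unique(y)
    if len(classes) != 2 or any(np.sum(y == c) < 2 for c in classes):
        raise ValueError("need binary labels with >= 2 samples per class")
    rng = np.random.default_rng(seed)
    w = np.ones(p)
    t = 0
    for _ in range(n_passes):
        for i in rng.permutation(n):
            t += 1
            w2 = w**2
            d2 = ((X - X[i]) ** 2) @ w2
            d2[i] = np.inf
            same = y == y[i]
            d2_hit = np.where(same, d2, np.inf)
            d2_miss = np.where(~same, d2, np.inf)
            nh = int(np.argmin(d2_hit))
            nm = int(np.argmin(d2_miss))
            dh = float(np.sqrt(max(d2[nh], 1e-12)))
            dm = float(np.sqrt(max(d2[nm], 1e-12)))
            gh = (X[i] - X[nh]) ** 2 / dh
            gm = (X[i] - X[nm]) ** 2 / dm
            w = w + (learning_rate / np.sqrt(t)) * 0.5 * (gm - gh) * w
    scores = w**2
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(method="simba", order=order, scores=scores)


@dataclass
class VoteTally:
    votes: np.ndarray            # per-feature count of top-k appearances
    final_order: np.ndarray      # features by descending votes
    mean_rank: np.ndarray        # mean within-run rank (tie-break key)
    top_k: int = 30

    def top(self, k: int) -> np.ndarray:
        return self.final_order[:k]


def vote(rankings: list[FeatureRanking], top_k: int = 30) -> VoteTally:
    """Aggregate per-run rankings: one vote per top-``top_k`` appearance.

    Final order: descending votes, ties by ascending mean within-run rank,
    remaining ties by feature index.
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    p = len(rankings[0].order)
    if any(len(r.order) != p for r in rankings):
        raise ValueError("rankings cover different feature sets")
    votes = np.zeros(p, dtype=int)
    rank_sum = np.zeros(p)
    for r in rankings:
        votes[r.order[:top_k]] += 1
        pos = np.empty(p)
        pos[r.order] = np.arange(p)
        rank_sum += pos
    mean_rank = rank_sum / len(rankings)
    final = sorted(range(p), key=lambda j: (-votes[j], mean_rank[j], j))
    return VoteTally(votes=votes, final_order=np.asarray(final),
                     mean_rank=mean_rank, top_k=top_k)


@dataclass
class PCAProjector:
    scaler: StandardScaler = field(repr=False)
    pca: PCA = field(repr=False)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))


def pca_project(X_train: np.ndarray, X_apply: np.ndarray,
                n_components: int = 30
                ) -> tuple[np.ndarray, np.ndarray, PCAProjector]:
    """Project onto the leading principal components fit on training data."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] <= n_components:
        raise ValueError("need more training samples than components")
    scaler = StandardScaler().fit(X_train)
    n_comp = min(n_components, min(X_train.shape))
    pca = PCA(n_components=n_comp).fit(scaler.transform(X_train))
    proj = PCAProjector(scaler=scaler, pca=pca)
    return proj.transform(X_train), proj.transform(np.asarray(X_apply, dtype=float)), proj
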