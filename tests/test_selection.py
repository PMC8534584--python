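"""Feature rankers, vote aggregation, and the PCA alternative."""

import collections

import numpy as np
import pytest

from phonoscreen.selection import (gso_rank, pca_project, relief_rank,
                                   simba_rank, vote)


def orthogonal_standardized_columns(n=120, p=8, seed=0):
    """Exactly orthogonal zero-mean columns (orthogonal after scaling too)."""
    rng = np.random.default_rng(seed)
    M = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    Q, _ = np.linalg.qr(M)
    X = Q[:, 1:]          # orthogonal to the constant => zero mean
    return X / X.std(axis=0)


class TestGSO:
    def test_label_copy_selected_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 50))
        X[:, 17] = y.astype(float)
        assert gso_rank(X, y).order[0] == 17

    def test_orthogonal_columns_follow_correlation_order(self):
        X = orthogonal_standardized_columns()
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, len(X))
        ranking = gso_rank(X, y, k=X.shape[1])
        yv = np.where(y > 0, 1.0, -1.0)
        yv -= yv.mean()
        corr = np.abs(X.T @ yv)
        assert np.array_equal(ranking.order, np.argsort(-corr))

    def test_duplicate_feature_residual_collapses(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 5))
        X[:, 1] = X[:, 0]
        y = (X[:, 0] > 0).astype(int)
        ranking = gso_rank(X, y, k=2)
        first = ranking.order[0]
        dup = 1 - first if first in (0, 1) else None
        assert dup is not None
        assert ranking.scores[dup] < 1e-6

    def test_order_is_permutation(self):
        rng = np.random.default_rng(2)
        r = gso_rank(rng.standard_normal((80, 20)), rng.integers(0, 2, 80))
        assert sorted(r.order.tolist()) == list(range(20))


class TestRelief:
    def test_informative_feature_wins_monte_carlo(self):
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            y = rng.integers(0, 2, 400)
            X = rng.standard_normal((400, 30))
            X[:, 7] = y + 0.3 * rng.standard_normal(400)
            wins += relief_rank(X, y).order[0] == 7
        assert wins >= 95

    def test_constant_feature_zero_weight(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 5))
        X[:, 2] = 3.3
        assert relief_rank(X, rng.integers(0, 2, 100)).scores[2] == 0.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((80, 10))
        y = rng.integers(0, 2, 80)
        perm = rng.permutation(80)
        a = relief_rank(X, y).scores
        b = relief_rank(X[perm], y[perm]).scores
        assert np.allclose(a, b)

    def test_feature_reorder_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 12))
        y = rng.integers(0, 2, 100)
        perm = rng.permutation(12)
        a = relief_rank(X, y).scores
        b = relief_rank(X[:, perm], y).scores
        assert np.allclose(a[perm], b)


class TestSimba:
    def test_informative_feature_wins_monte_carlo(self):
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(100 + rep)
            y = rng.integers(0, 2, 400)
            X = rng.standard_normal((400, 30))
            X[:, 7] = y + 0.3 * rng.standard_normal(400)
            wins += simba_rank(X, y, seed=rep).order[0] == 7
        assert wins >= 95

    def test_identical_copies_symmetric_weights(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((200, 1))
        X = base @ np.ones((1, 4)) + 0.01 * rng.standard_normal((200, 4))
        y = (base[:, 0] > 0).astype(int)
        w2 = simba_rank(X, y, seed=1).scores
        assert (w2.max() - w2.min()) / w2.max() < 0.10

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((150, 20))
        y = rng.integers(0, 2, 150)
        assert np.array_equal(simba_rank(X, y, seed=4).order,
                              simba_rank(X, y, seed=4).order)


class TestVote:
    def test_identical_rankings_preserved(self):
        rng = np.random.default_rng(10)
        r = gso_rank(rng.standard_normal((60, 40)), rng.integers(0, 2, 60))
        tally = vote([r, r, r], top_k=30)
        assert np.array_equal(tally.final_order[:30], r.order[:30])

    def test_always_top30_gets_all_votes(self):
        rankings = [gso_rank(np.random.default_rng(s).standard_normal((60, 40)),
                             np.random.default_rng(s).integers(0, 2, 60))
                    for s in range(5)]
        tally = vote(rankings, top_k=30)
        everywhere = set(rankings[0].order[:30])
        for r in rankings[1:]:
            everywhere &= set(r.order[:30])
        for j in everywhere:
            assert tally.votes[j] == 5

    def test_matches_brute_force_tally(self):
        rankings = [gso_rank(np.random.default_rng(s).standard_normal((50, 35)),
                             np.random.default_rng(s).integers(0, 2, 50))
                    for s in range(3)]
        tally = vote(rankings, top_k=30)
        counter = collections.Counter()
        for r in rankings:
            counter.update(r.order[:30].tolist())
        assert all(tally.votes[j] == counter.get(j, 0) for j in range(35))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vote([])


class TestRankersRecoverPlantedSignal:
    """5 informative features among 304; voting over folds finds them."""

    @pytest.mark.parametrize("ranker", [
        lambda X, y: gso_rank(X, y),
        lambda X, y: relief_rank(X, y),
        lambda X, y: simba_rank(X, y, seed=0),
    ], ids=["gso", "relief", "simba"])
    def test_vote_top10_contains_all_informative(self, ranker):
        from phonoscreen.pipeline import voted_ranker
        hits = 0
        reps = 5
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            n = 600
            y = np.repeat([0, 1], n // 2)
            X = rng.standard_normal((n, 304))
            X[y == 1, :5] += 1.0
            ranking = voted_ranker(ranker, folds=10, seed=rep)(X, y)
            hits += set(range(5)) <= set(ranking.order[:10].tolist())
        assert hits >= int(0.8 * reps)


class TestPCA:
    def test_training_variance_non_increasing(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 40)) * np.linspace(5, 0.1, 40)
        Z, _, proj = pca_project(X, X)
        var = Z.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_rank2_data_trailing_components_empty(self):
        rng = np.random.default_rng(12)
        basis = rng.standard_normal((2, 30))
        X = rng.standard_normal((80, 2)) @ basis
        Z, _, _ = pca_project(X, X, n_components=10)
        assert np.all(Z.var(axis=0)[2:] < 1e-12)

    def test_full_rank_reconstruction_exact(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((50, 8))
        Z, _, proj = pca_project(X, X, n_components=8)
        Xr = proj.scaler.inverse_transform(proj.pca.inverse_transform(Z))
        assert np.allclose(Xr, X, atol=1e-9)

    def test_projection_fit_on_train_only(self):
        rng = np.random.default_rng(14)
        X_train = rng.standard_normal((60, 10))
        X_test = rng.standard_normal((20, 10)) + 5.0
        _, Zt, proj = pca_project(X_train, X_test, n_components=3)
        assert np.allclose(Zt, proj.transform(X_test))
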