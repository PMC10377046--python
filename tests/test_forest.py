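"""Two-stage graph forest: stump counts, pool containment, importance, baseline."""

import numpy as np
import pytest

from graphrf import (
    FeatureGraph,
    GraphRandomForestClassifier,
    HeadNodeCounts,
    aggregate_importance,
    fit_grf,
    fit_stump_forest,
    fit_vanilla_rf,
    generate_ba_graph,
    k_hop_neighborhood,
    roc_auc,
    simulate_dataset,
)


def _separable_data(n=80, p=12, seed=0):
    """Feature 0 perfectly separates the classes; the rest is noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[:, 0] = np.where(y == 1, 5.0, -5.0) + 0.1 * rng.standard_normal(n)
    return X, y


# ---------------------------------------------------------------- stump forest

class TestFitStumpForest:
    def test_perfect_feature_wins_every_stump(self):
        X, y = _separable_data()
        counts = fit_stump_forest(X, y, n_stumps=50, mtry=X.shape[1], seed=0)
        assert counts.counts[0] == 50
        assert counts.total == 50

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 30))
        y = rng.integers(0, 2, 60)
        counts = fit_stump_forest(X, y, n_stumps=200, seed=1)
        assert counts.total == 200
        assert np.all(counts.counts >= 0)

    def test_pure_noise_spreads_counts(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 200))
        y = rng.integers(0, 2, 100)
        counts = fit_stump_forest(X, y, n_stumps=300, seed=2)
        assert counts.counts.max() < 100  # no single noise feature dominates
        assert (counts.counts > 0).sum() > 20

    def test_all_constant_matrix_rejected(self):
        X = np.ones((20, 5))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="constant"):
            fit_stump_forest(X, y, n_stumps=10, seed=0)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 5))
        with pytest.raises(ValueError, match="two classes"):
            fit_stump_forest(X, np.zeros(20), n_stumps=10)


# ------------------------------------------------------------------ GRF fitting

class TestFitGRF:
    def test_saturated_hop_uses_full_feature_set(self):
        X, y = _separable_data(p=6)
        g = FeatureGraph.from_edges(6, [(i, i + 1) for i in range(5)])  # diameter 5
        model = fit_grf(X, y, g, k=6, n_stumps=30, seed=0)
        for sf in model.sub_forests:
            assert sf.pool.tolist() == list(range(6))

    def test_hop_zero_pools_are_singleton_heads(self):
        X, y = _separable_data(p=6)
        g = FeatureGraph.from_edges(6, [(i, i + 1) for i in range(5)])
        model = fit_grf(X, y, g, k=0, n_stumps=30, seed=0)
        for sf in model.sub_forests:
            assert sf.pool.tolist() == [sf.head]

    def test_single_head_gets_whole_budget(self):
        X, y = _separable_data(p=6)
        g = FeatureGraph.from_edges(6, [(i, i + 1) for i in range(5)])
        counts = np.zeros(6, dtype=int)
        counts[2] = 40
        model = fit_grf(X, y, g, k=1, counts=HeadNodeCounts(counts), seed=0)
        assert len(model.sub_forests) == 1
        assert model.sub_forests[0].n_trees == 40
        assert model.n_trees == 40

    def test_tree_budget_conserved(self, small_dataset):
        d = small_dataset
        counts = fit_stump_forest(d.X, d.y, n_stumps=100, seed=5)
        model = fit_grf(d.X, d.y, d.graph, k=2, counts=counts, seed=5)
        assert model.n_trees == counts.total == 100

    def test_every_split_feature_inside_its_pool(self, small_dataset):
        # exhaustive tree walk: all split features must map into the pool
        d = small_dataset
        model = fit_grf(d.X, d.y, d.graph, k=2, n_stumps=80, seed=9)
        for sf in model.sub_forests:
            pool = set(range(len(sf.pool)))  # local column space of the pool
            for tree in sf.estimator.estimators_:
                feats = tree.tree_.feature
                used = set(feats[feats >= 0].tolist())
                assert used <= pool
                assert {int(sf.pool[f]) for f in used} <= set(sf.pool.tolist())

    def test_pool_union_monotone_in_k(self, small_dataset):
        d = small_dataset
        counts = fit_stump_forest(d.X, d.y, n_stumps=60, seed=3)
        unions = []
        for k in (0, 1, 2, 3):
            model = fit_grf(d.X, d.y, d.graph, k=k, counts=counts, seed=3)
            unions.append(set().union(*(set(sf.pool.tolist()) for sf in model.sub_forests)))
        for a, b in zip(unions, unions[1:]):
            assert a <= b

    def test_dimension_mismatch(self):
        X, y = _separable_data(p=6)
        g = FeatureGraph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        with pytest.raises(ValueError, match="graph"):
            fit_grf(X, y, g, k=1, n_stumps=10, seed=0)


# ------------------------------------------------------------------- prediction

class _ConstantForest:
    """Duck-typed stand-in estimator returning a fixed class-1 probability."""

    def __init__(self, p1, classes=(0, 1)):
        self.p1 = p1
        self.classes_ = np.array(classes)

    def predict_proba(self, X):
        return np.tile([1 - self.p1, self.p1], (len(X), 1))


def _manual_model(probs_and_counts, p=4):
    from graphrf.forest import GRFModel, SubForest

    g = FeatureGraph.from_edges(p, [(i, i + 1) for i in range(p - 1)])
    subs = tuple(
        SubForest(head=i, pool=np.arange(p), n_trees=c, estimator=_ConstantForest(p1))
        for i, (p1, c) in enumerate(probs_and_counts)
    )
    return GRFModel(
        sub_forests=subs, hop=1, classes=np.array([0, 1]), n_features=p,
        max_depth=None, graph=g,
    )


class TestPredict:
    def test_unanimous_class_one(self):
        model = _manual_model([(1.0, 3), (1.0, 2)])
        X = np.zeros((5, 4))
        assert np.all(model.decision_scores(X) == 1.0)
        assert np.all(model.predict(X) == 1)

    def test_exact_tie_breaks_to_class_zero(self):
        model = _manual_model([(0.5, 2), (0.5, 2)])
        X = np.zeros((3, 4))
        assert np.all(model.decision_scores(X) == 0.5)
        assert np.all(model.predict(X) == 0)

    def test_scores_weighted_by_tree_counts(self):
        # 3 trees at p1=1.0 and 1 tree at p1=0.0 -> score 0.75
        model = _manual_model([(1.0, 3), (0.0, 1)])
        assert model.decision_scores(np.zeros((1, 4)))[0] == pytest.approx(0.75)

    def test_misaligned_columns_rejected(self, small_dataset):
        d = small_dataset
        model = fit_grf(d.X, d.y, d.graph, k=1, n_stumps=20, seed=0)
        with pytest.raises(ValueError, match="columns"):
            model.predict(d.X[:, :50])

    def test_training_fit_beats_chance(self, small_dataset):
        d = small_dataset
        clf = GraphRandomForestClassifier(d.graph, hop=2, n_trees=120, seed=1)
        clf.fit(d.X, d.y)
        assert (clf.predict(d.X) == d.y).mean() > 0.8  # in-sample fit


# ------------------------------------------------------------------ importance

class TestAggregateImportance:
    def test_single_subforest_equals_weighted_normalized_gini(self, small_dataset):
        d = small_dataset
        counts = np.zeros(d.config.p, dtype=int)
        counts[int(d.S[0])] = 25
        model = fit_grf(d.X, d.y, d.graph, k=2, counts=HeadNodeCounts(counts), seed=2)
        sf = model.sub_forests[0]
        imp = aggregate_importance(model)
        gini = sf.estimator.feature_importances_
        gini = gini / gini.sum()
        assert np.allclose(imp[sf.pool], 25 * gini)
        outside = np.setdiff1d(np.arange(d.config.p), sf.pool)
        assert np.all(imp[outside] == 0)

    def test_disjoint_pools_concatenate(self):
        # two far-apart heads on a long path: pools are disjoint, so the total
        # importance is the sum of the two weighted vectors
        X, y = _separable_data(n=100, p=20)
        g = FeatureGraph.from_edges(20, [(i, i + 1) for i in range(19)])
        counts = np.zeros(20, dtype=int)
        counts[0], counts[19] = 12, 8
        model = fit_grf(X, y, g, k=1, counts=HeadNodeCounts(counts), seed=4)
        pools = [set(sf.pool.tolist()) for sf in model.sub_forests]
        assert pools[0].isdisjoint(pools[1])
        imp = aggregate_importance(model)
        assert imp.sum() == pytest.approx(12 + 8)

    def test_support_restricted_to_pool_union(self, small_dataset):
        d = small_dataset
        model = fit_grf(d.X, d.y, d.graph, k=1, n_stumps=50, seed=6)
        union = set().union(*(set(sf.pool.tolist()) for sf in model.sub_forests))
        imp = aggregate_importance(model)
        assert set(np.flatnonzero(imp).tolist()) <= union


# --------------------------------------------------------------------- baseline

class TestVanillaRF:
    def test_signal_feature_tops_importance(self):
        X, y = _separable_data()
        rf = fit_vanilla_rf(X, y, n_trees=50, seed=0)
        imp = rf.feature_importances()
        assert imp.argmax() == 0
        assert imp.sum() == pytest.approx(1.0)

    def test_tree_budget_and_depth(self):
        X, y = _separable_data()
        rf = fit_vanilla_rf(X, y, n_trees=500, max_depth=10, seed=0)
        assert rf.n_trees == 500
        assert all(t.get_depth() <= 10 for t in rf.estimator.estimators_)

    def test_predictions_match_reference_forest(self):
        # cross-check against an independently seeded majority-vote forest
        from sklearn.ensemble import RandomForestClassifier

        X, y = _separable_data(n=120, p=8, seed=5)
        rf = fit_vanilla_rf(X, y, n_trees=100, seed=1)
        ref = RandomForestClassifier(
            n_estimators=100, max_depth=10, max_features=3, random_state=99
        ).fit(X, y)
        agree = (rf.predict(X) == ref.predict(X)).mean()
        assert agree > 0.95  # separable data: vote-level stochastic tolerance


# --------------------------------------------------- graph advantage (scaled)

def test_grf_importance_beats_rf_on_majority_of_replicates():
    """Network-guided selection outranks the baseline in most paired replicates."""
    wins = 0
    reps = 5
    for seed in range(reps):
        data = simulate_dataset(p=600, n=250, p0=30, seed=100 + seed)
        clf = GraphRandomForestClassifier(data.graph, hop=3, n_trees=300, seed=seed)
        clf.fit(data.X, data.y)
        rf = fit_vanilla_rf(data.X, data.y, n_trees=300, seed=seed)
        auc_g = roc_auc(clf.feature_importances_, data.true_indicator)
        auc_r = roc_auc(rf.feature_importances(), data.true_indicator)
        wins += auc_g > auc_r
    assert wins > reps / 2
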