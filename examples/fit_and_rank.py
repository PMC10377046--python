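"""Fit a Graph Random Forest and compare its feature ranking with a vanilla RF.

Both models get the same 500-tree budget and the same training split; quality
is the rank-based AUC of the importance vector against the indicator of the
true-predictor set (1.0 = every true predictor outranks every other feature).
"""

from graphrf import (
    GraphRandomForestClassifier,
    fit_vanilla_rf,
    pr_auc,
    roc_auc,
    simulate_dataset,
    split_train_test,
)

data = simulate_dataset(p=1000, n=300, p0=40, seed=7)
X_tr, X_te, y_tr, y_te = split_train_test(data.X, data.y, ratio=0.7, seed=7)
truth = data.true_indicator

grf = GraphRandomForestClassifier(data.graph, hop=3, n_trees=500, seed=7)
grf.fit(X_tr, y_tr)
rf = fit_vanilla_rf(X_tr, y_tr, n_trees=500, max_depth=10, seed=7)

heads = grf.head_counts_.head_nodes
print(f"stage 1: {grf.head_counts_.total} stumps over {len(heads)} head nodes")
print(f"stage 2: {grf.model_.n_trees} trees in {len(grf.model_.sub_forests)} sub-forests")
for name, model, imp in [
    ("GRF hop-3", grf, grf.feature_importances_),
    ("vanilla RF", rf, rf.feature_importances()),
]:
    acc = (model.predict(X_te) == y_te).mean()
    print(f"{name:>10}: test accuracy {acc:.2f}, importance AUC {roc_auc(imp, truth):.3f}, "
          f"PR-AUC {pr_auc(imp, truth):.3f}")
# Comparable accuracy, much better ranking: the graph constraint concentrates
# importance on the true module instead of scattered correlated proxies.
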