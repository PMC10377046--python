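# graphrf — Graph Random Forest

Network-guided random forests for identifying **highly connected important
features** in omics classification problems.

Molecular features (genes, proteins, miRNAs) act through interaction networks:
the signal that separates two disease states usually lives on a *connected
sub-graph*, and features are correlated with their network neighbors. A vanilla
random forest ignores this and tends to pick scattered, redundant proxies.
`graphrf` embeds the network directly into forest construction so that the
features it selects form coherent modules on the interaction graph — the
objects a biologist can actually interpret and follow up.

## The method

Training a **Graph Random Forest (GRF)** on `(X, y)` with feature graph
`G = (V, E)` has two stages sharing one tree budget (default 500):

1. **Head-node allocation.** Fit 500 depth-one trees (Gini splits, bootstrap,
   `mtry = ⌈√p⌉`) and record `c_i`, the number of stumps whose root split uses
   feature `i`.
2. **Neighborhood-restricted sub-forests.** For every head node `i` with
   `c_i > 0`, fit a forest `F_i` of `c_i` trees whose split candidates are
   restricted to `Neighbor(i, k)` — all features within `k` hops of `i`
   (inclusive). The model therefore has exactly `Σ c_i = 500` trees.

Feature importance starts at `I = 0` and aggregates per sub-forest:

    I_j ← I_j + c_i · imp_j^(i),   j ∈ Neighbor(i, k),

where `imp^(i)` is `F_i`'s Gini (mean-decrease-in-impurity) importance,
normalized to sum to one over the pool. Features outside every pool keep
importance exactly zero, which structurally confines selection to network
vicinities of data-nominated head nodes. Prediction averages class
probabilities over all 500 trees; ties break to class 0.

The package also ships the matching simulation study: a scale-free graph
(preferential attachment with kernel `degree^0.5`), feature covariance
`Σ_ij = 0.8^{D_ij}` (hop distance `D`), mean-zero Gaussian expression, a
connected true-predictor sub-graph grown from high-degree cores, binary
outcomes via logistic or absolute links, plus ranking metrics (ROC-AUC /
PR-AUC of importance against the true-predictor indicator), induced-sub-graph
connectivity reports, a benchmark grid and a selection-stability experiment.

## Worked example

```python
from graphrf import (GraphRandomForestClassifier, fit_vanilla_rf, roc_auc,
                     simulate_dataset, split_train_test)

data = simulate_dataset(p=1000, n=300, p0=40, seed=7)   # 40 true predictors
X_tr, X_te, y_tr, y_te = split_train_test(data.X, data.y, ratio=0.7, seed=7)

grf = GraphRandomForestClassifier(data.graph, hop=3, n_trees=500, seed=7)
grf.fit(X_tr, y_tr)
rf = fit_vanilla_rf(X_tr, y_tr, n_trees=500, max_depth=10, seed=7)

print(roc_auc(grf.feature_importances_, data.true_indicator))
print(roc_auc(rf.feature_importances(), data.true_indicator))
```

Running `python examples/fit_and_rank.py` (the same computation) prints:

```
stage 1: 500 stumps over 211 head nodes
stage 2: 500 trees in 211 sub-forests
 GRF hop-3: test accuracy 0.66, importance AUC 0.899, PR-AUC 0.303
vanilla RF: test accuracy 0.69, importance AUC 0.768, PR-AUC 0.201
```

Classification accuracy is comparable, but the graph forest ranks the true
predictors far higher (AUC 0.90 vs 0.77): the network constraint concentrates
importance on the generating module instead of scattered correlated proxies.
`python examples/subgraph_connectivity.py` shows the flip side — the top-100
GRF features induce one 99-node connected component (density 0.020) while the
vanilla RF's top-100 fragment into 53 components (density 0.010).

More narrative scripts live in `examples/`: dataset generation, sub-graph
connectivity, selection stability across refits, and a file-based workflow
(read → log-transform → harmonize to the network's largest connected
component → fit).

## Command line

A thin CLI wraps the same library calls:

```bash
graphrf simulate --p 1000 --n 300 --p0 40 --seed 7 --out-dir sim/
graphrf fit --expression sim/expression.tsv --labels sim/labels.tsv \
            --network sim/network.tsv --hop 2 --trees 500 --out-dir fit/
graphrf benchmark --p 500 --n 200 --p0 20 --reps 3 --out-dir bench/
graphrf stability --p 1000 --n 300 --p0 60 --repeats 10 --out-dir stab/
```

Every run writes a JSON manifest (resolved options, seed, library versions)
next to its outputs.

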