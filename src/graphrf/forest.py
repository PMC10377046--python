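"""Graph Random Forest: stump-allocated, neighborhood-restricted sub-forests.

Training is two-stage. Stage 1 fits a forest of depth-one trees (stumps) and
records how often each feature is chosen as the root ("head") split; these
counts ``c_i`` are a data-driven measure of which graph regions carry signal.
Stage 2 builds, for every head node ``i`` with ``c_i > 0``, a random forest
``F_i`` of ``c_i`` trees whose split candidates are restricted to the k-hop
graph neighborhood of ``i``. The total tree budget is conserved: the stage-2
model has exactly as many trees as stage 1 fitted stumps (500 by default).

Feature importance is the ``c_i``-weighted sum of each sub-forest's normalized
mean-decrease-in-impurity (Gini) importance, so features can only accumulate
importance inside neighborhoods that earned trees — the mechanism that makes
the selected features form connected modules in the network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .graph import FeatureGraph, k_hop_neighborhood

__all__ = [
    "HeadNodeCounts",
    "SubForest",
    "GRFModel",
    "fit_stump_forest",
    "fit_grf",
    "aggregate_importance",
    "fit_vanilla_rf",
    "VanillaRF",
    "GraphRandomForestClassifier",
]

_MAX_STUMP_ATTEMPTS = 10


def _default_mtry(n_features: int) -> int:
    return min(n_features, math.ceil(math.sqrt(n_features)))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x features matrix")
    if y.shape != (X.shape[0],):
        raise ValueError(f"y length {y.shape} does not match n={X.shape[0]}")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    return X, y, classes


@dataclass(frozen=True)
class HeadNodeCounts:
    """Per-feature counts of head-splitting-node occurrences in the stump forest.

    ``counts[j]`` is the number of stage-1 stumps whose root split used feature
    ``j``; ``total`` (= sum of counts) equals the number of successfully fitted
    stumps and becomes the stage-2 tree budget.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def head_nodes(self) -> np.ndarray:
        """Indices with nonzero counts, ascending."""
        return np.flatnonzero(self.counts)


def fit_stump_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_stumps: int = 500,
    mtry: int | None = None,
    seed: int | np.random.Generator = 0,
) -> HeadNodeCounts:
    """Stage 1: fit ``n_stumps`` depth-one trees and count root-split features.

    Each stump is trained on a bootstrap resample (expressed as multinomial
    sample weights) with ``mtry`` random split candidates scored by Gini
    impurity decrease; default mtry is ceil(sqrt(p)). A stump whose bootstrap
    admits no valid split (e.g. single-class resample) is redrawn up to a
    bounded number of attempts and then dropped with a warning, in which case
    ``total`` reflects only fitted stumps.
    """
    X, y, classes = _check_xy(X, y)
    if n_stumps < 1:
        raise ValueError(f"n_stumps must be >= 1, got {n_stumps}")
    n, p = X.shape
    if np.all(X == X[0, :], axis=0).all():
        raise ValueError("all features are constant; no stump can split")
    mtry = _default_mtry(p) if mtry is None else min(mtry, p)
    rng = _as_rng(seed)

    counts = np.zeros(p, dtype=np.int64)
    dropped = 0
    for _ in range(n_stumps):
        root = -1
        for _attempt in range(_MAX_STUMP_ATTEMPTS):
            w = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(np.float64)
            tree = DecisionTreeClassifier(
                max_depth=1,
                max_features=mtry,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X, y, sample_weight=w)
            root = int(tree.tree_.feature[0])
            if root >= 0:
                break
        if root >= 0:
            counts[root] += 1
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} of {n_stumps} stumps found no valid split and were dropped",
            RuntimeWarning,
        )
    if counts.sum() == 0:
        raise ValueError("no stump produced a valid split")
    return HeadNodeCounts(counts)


@dataclass(frozen=True)
class SubForest:
    """A head node, its k-hop feature pool, and the forest of ``n_trees`` trees on it."""

    head: int
    pool: np.ndarray  # sorted feature indices, always containing `head`
    n_trees: int
    estimator: RandomForestClassifier


@dataclass(frozen=True)
class GRFModel:
    """A fitted Graph Random Forest: one neighborhood-restricted forest per head node."""

    sub_forests: tuple[SubForest, ...]
    hop: int
    classes: np.ndarray
    n_features: int
    max_depth: int | None
    graph: FeatureGraph = field(repr=False)

    @property
    def n_trees(self) -> int:
        return sum(sf.n_trees for sf in self.sub_forests)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Class-1 score per sample: tree-count-weighted mean class-1 probability."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"X must have {self.n_features} columns aligned to training features"
            )
        score = np.zeros(X.shape[0])
        total = self.n_trees
        for sf in self.sub_forests:
            proba = sf.estimator.predict_proba(X[:, sf.pool])
            col = list(sf.estimator.classes_).index(self.classes[1])
            score += sf.n_trees / total * proba[:, col]
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels; a score of exactly 0.5 breaks to the first class."""
        score = self.decision_scores(X)
        return np.where(score > 0.5, self.classes[1], self.classes[0])

    def feature_importances(self) -> np.ndarray:
        return aggregate_importance(self)


def fit_grf(
    X: np.ndarray,
    y: np.ndarray,
    graph: FeatureGraph,
    k: int = 2,
    counts: HeadNodeCounts | None = None,
    max_depth: int | None = 10,
    seed: int | np.random.Generator = 0,
    n_stumps: int = 500,
) -> GRFModel:
    """Stage 2: fit one forest of ``c_i`` trees per head node on its k-hop pool.

    ``counts`` normally comes from :func:`fit_stump_forest`; when omitted the
    stump stage is run here first (same seed stream) with ``n_stumps`` trees.
    Within each sub-forest, trees use bootstrap resampling and per-node
    mtry = ceil(sqrt(pool size)).
    """
    X, y, classes = _check_xy(X, y)
    if X.shape[1] != graph.node_count:
        raise ValueError(
            f"X has {X.shape[1]} features but the graph has {graph.node_count} nodes"
        )
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    rng = _as_rng(seed)
    if counts is None:
        counts = fit_stump_forest(X, y, n_stumps=n_stumps, seed=rng)
    if counts.counts.shape[0] != graph.node_count:
        raise ValueError("head-node counts are not aligned to the graph")
    if counts.total < 1:
        raise ValueError("head-node counts contain no trees")

    subs: list[SubForest] = []
    for head in counts.head_nodes:
        pool = np.array(sorted(k_hop_neighborhood(graph, int(head), k)), dtype=np.int64)
        c = int(counts.counts[head])
        est = RandomForestClassifier(
            n_estimators=c,
            max_depth=max_depth,
            max_features=_default_mtry(len(pool)),
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        est.fit(X[:, pool], y)
        subs.append(SubForest(head=int(head), pool=pool, n_trees=c, estimator=est))
    return GRFModel(
        sub_forests=tuple(subs),
        hop=k,
        classes=classes,
        n_features=graph.node_count,
        max_depth=max_depth,
        graph=graph,
    )


def aggregate_importance(model: GRFModel) -> np.ndarray:
    """Length-p importance vector ``I``: ``I_j += c_i * imp_j^(i)`` over sub-forests.

    Each sub-forest's Gini (mean decrease in impurity) importance is normalized
    to sum to 1 over its pool before weighting, so sub-forests with different
    pool sizes contribute on the same scale. Features outside every pool stay
    exactly 0.
    """
    I = np.zeros(model.n_features)
    for sf in model.sub_forests:
        imp = sf.estimator.feature_importances_
        s = imp.sum()
        if s > 0:
            imp = imp / s
        I[sf.pool] += imp * sf.n_trees
    return I


@dataclass(frozen=True)
class VanillaRF:
    """The comparison arm: a standard 500-tree depth-10 Gini random forest."""

    estimator: RandomForestClassifier
    classes: np.ndarray

    @property
    def n_trees(self) -> int:
        return len(self.estimator.estimators_)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(np.asarray(X, dtype=np.float64))
        col = list(self.estimator.classes_).index(self.classes[1])
        return proba[:, col]

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_scores(X)
        return np.where(score > 0.5, self.classes[1], self.classes[0])

    def feature_importances(self) -> np.ndarray:
        imp = self.estimator.feature_importances_
        s = imp.sum()
        return imp / s if s > 0 else imp.copy()


def fit_vanilla_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    max_depth: int | None = 10,
    mtry: int | None = None,
    seed: int | np.random.Generator = 0,
) -> VanillaRF:
    """Fit the baseline random forest (Gini splits, bootstrap, mtry=ceil(sqrt(p)))."""
    X, y, classes = _check_xy(X, y)
    rng = _as_rng(seed)
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features=_default_mtry(X.shape[1]) if mtry is None else mtry,
        bootstrap=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    est.fit(X, y)
    return VanillaRF(estimator=est, classes=classes)


class GraphRandomForestClassifier:
    """Convenience wrapper running both training stages with one seed.

    Parameters
    ----------
    graph
        The feature-interaction graph; columns of X must align to its nodes.
    hop
        Neighborhood radius k for the sub-forest feature pools.
    n_trees
        Total tree budget; also the stage-1 stump count, so the budget is
        conserved between stages.
    max_depth
        Depth cap for stage-2 trees (stumps are always depth 1).
    """

    def __init__(
        self,
        graph: FeatureGraph,
        hop: int = 2,
        n_trees: int = 500,
        max_depth: int | None = 10,
        seed: int = 0,
    ) -> None:
        self.graph = graph
        self.hop = hop
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.seed = seed
        self.head_counts_: HeadNodeCounts | None = None
        self.model_: GRFModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GraphRandomForestClassifier":
        rng = np.random.default_rng(self.seed)
        self.head_counts_ = fit_stump_forest(X, y, n_stumps=self.n_trees, seed=rng)
        self.model_ = fit_grf(
            X, y, self.graph, k=self.hop, counts=self.head_counts_,
            max_depth=self.max_depth, seed=rng,
        )
        return self

    def _fitted(self) -> GRFModel:
        if self.model_ is None:
            raise RuntimeError("call fit() first")
        return self.model_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._fitted().predict(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self._fitted().decision_scores(X)

    @property
    def feature_importances_(self) -> np.ndarray:
        return aggregate_importance(self._fitted())
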