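"""Classification / feature-ranking metrics, the benchmark grid, and stability runs.

Feature-selection quality is scored by ranking all p features by estimated
importance against the indicator of the true-predictor set S: ROC-AUC (the
probability a random true predictor outranks a random non-predictor, ties
counting one half) and PR-AUC (average precision). Connectivity of a selected
feature set is scored through the induced sub-graph (density, components,
largest component). The stability experiment refits the model R times on one
fixed dataset, varying only the fitting seed, and summarizes how reproducible
the top-K list is and how it relates to S and its one-hop closure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .forest import GraphRandomForestClassifier, fit_vanilla_rf
from .graph import FeatureGraph, induced_subgraph_metrics
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset

__all__ = [
    "split_train_test",
    "roc_auc",
    "pr_auc",
    "top_k_features",
    "one_hop_closure",
    "StabilityReport",
    "stability_experiment",
    "run_benchmark",
]


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    ratio: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random (by default stratified) train/test split; returns X_tr, X_te, y_tr, y_te."""
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError(f"need at least 10 samples, got {len(y)}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    return train_test_split(
        np.asarray(X), y,
        train_size=ratio,
        random_state=seed,
        stratify=y if stratify else None,
    )


def _check_ranking(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (normalized Mann-Whitney U; ties count one half)."""
    scores, labels = _check_ranking(scores, labels)
    if np.unique(labels).size != 2:
        raise ValueError("roc_auc needs both label classes present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-wise PR area, no trapezoidal interpolation)."""
    scores, labels = _check_ranking(scores, labels)
    if np.sum(labels == np.max(labels)) == 0 or np.unique(labels).size < 2:
        raise ValueError("pr_auc needs at least one positive and one negative label")
    return float(average_precision_score(labels, scores))


def top_k_features(importance: Sequence[float], k: int = 100) -> np.ndarray:
    """Indices of the k largest importances, ascending-index tie-break, sorted."""
    imp = np.asarray(importance, dtype=np.float64)
    if k > imp.size:
        raise ValueError(f"k={k} exceeds p={imp.size}")
    order = np.argsort(-imp, kind="stable")  # stable: ties keep ascending index
    return np.sort(order[:k])


def one_hop_closure(graph: FeatureGraph, nodes: Iterable[int]) -> set[int]:
    """The node set together with every direct graph neighbor."""
    nodes = set(int(v) for v in nodes)
    return nodes | {nb for v in nodes for nb in graph.neighbors(v)}


@dataclass(frozen=True)
class StabilityReport:
    """Reproducibility of top-K selection across R refits of one dataset.

    ``appearance_counts[j]`` is in [0, R]; ``union`` is every feature that made
    at least one top-K list. ``frac_union_in_true`` and
    ``frac_union_within_one_hop`` compare the union with the true-predictor set
    S and its one-hop closure (the latter always contains the former).
    """

    n_repeats: int
    k_top: int
    appearance_counts: np.ndarray
    union: np.ndarray
    true_set: np.ndarray
    frac_union_in_true: float
    frac_union_within_one_hop: float

    def features_above(self, threshold: int) -> np.ndarray:
        """Features appearing in strictly more than ``threshold`` of the R lists."""
        return np.flatnonzero(self.appearance_counts > threshold)

    def n_above(self, threshold: int) -> int:
        return int(self.features_above(threshold).size)

    def n_true_above(self, threshold: int) -> int:
        """How many of the stably selected features are true predictors."""
        return int(np.isin(self.features_above(threshold), self.true_set).sum())


def stability_experiment(
    dataset: SimulatedDataset,
    n_repeats: int = 20,
    k_top: int = 100,
    hop: int = 2,
    n_trees: int = 500,
    max_depth: int | None = 10,
    seed: int = 0,
) -> StabilityReport:
    """Refit the graph forest R times on the same data, varying only the fit seed.

    The data, split and ground truth are held fixed; each repeat records its
    top ``k_top`` features by aggregated importance.
    """
    p = dataset.config.p
    counts = np.zeros(p, dtype=np.int64)
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_repeats):
        fit_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        clf = GraphRandomForestClassifier(
            dataset.graph, hop=hop, n_trees=n_trees, max_depth=max_depth, seed=fit_seed
        ).fit(dataset.X, dataset.y)
        counts[top_k_features(clf.feature_importances_, k_top)] += 1
    union = np.flatnonzero(counts)
    in_true = np.isin(union, dataset.S)
    closure = one_hop_closure(dataset.graph, dataset.S)
    in_closure = np.array([int(v) in closure for v in union])
    return StabilityReport(
        n_repeats=n_repeats,
        k_top=k_top,
        appearance_counts=counts,
        union=union,
        true_set=dataset.S,
        frac_union_in_true=float(in_true.mean()) if union.size else float("nan"),
        frac_union_within_one_hop=float(in_closure.mean()) if union.size else float("nan"),
    )


def _fit_method(method: str, data: SimulatedDataset, X_tr, y_tr, n_trees, max_depth, seed):
    """Fit 'rf' or 'grf-<hop>' and return (model, importance)."""
    if method == "rf":
        model = fit_vanilla_rf(X_tr, y_tr, n_trees=n_trees, max_depth=max_depth, seed=seed)
        return model, model.feature_importances()
    if method.startswith("grf-"):
        hop = int(method.split("-", 1)[1])
        clf = GraphRandomForestClassifier(
            data.graph, hop=hop, n_trees=n_trees, max_depth=max_depth, seed=seed
        ).fit(X_tr, y_tr)
        return clf, clf.feature_importances_
    raise ValueError(f"unknown method {method!r}; use 'rf' or 'grf-<hop>'")


def run_benchmark(
    p0_values: Sequence[int] = (30, 60, 90, 120, 150, 180, 210),
    n_cores_values: Sequence[int] = (1, 2),
    links: Sequence[str] = ("logistic", "absolute"),
    methods: Sequence[str] = ("rf", "grf-1", "grf-2", "grf-3"),
    reps: int = 10,
    base_config: SimulationConfig | None = None,
    n_trees: int = 500,
    max_depth: int | None = 10,
    k_top: int = 100,
    split_ratio: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the simulation benchmark grid and return one tidy row per replicate.

    Per cell (p0, n_cores, link) and replicate, one dataset is generated, split
    7:3, and every method is fit on the identical training data. Columns:
    test_accuracy, auc, pr_auc (importance vs true indicator), and the induced
    sub-graph report of the top ``k_top`` features. Replicate seeds derive from
    the master seed by a counter scheme, so any cell reruns identically in
    isolation. A failed replicate is recorded with an ``error`` entry, never
    silently dropped.
    """
    base = base_config or SimulationConfig()
    rows: list[dict] = []
    for p0 in p0_values:
        for n_cores in n_cores_values:
            for link in links:
                for rep in range(reps):
                    cell_seed = int(
                        np.random.SeedSequence(
                            entropy=seed,
                            spawn_key=(p0, n_cores, rep, *(ord(c) for c in link)),
                        ).generate_state(1)[0]
                        % (2**31 - 1)
                    )
                    common = dict(
                        p0=p0, n_cores=n_cores, link=link, rep=rep,
                        p=base.p, n=base.n, seed=cell_seed,
                    )
                    try:
                        data = simulate_dataset(
                            replace(base, p0=p0, n_cores=n_cores, link=link, seed=cell_seed)
                        )
                        X_tr, X_te, y_tr, y_te = split_train_test(
                            data.X, data.y, ratio=split_ratio, seed=cell_seed
                        )
                    except Exception as exc:  # record, do not drop
                        for method in methods:
                            rows.append({**common, "method": method, "error": str(exc)})
                        continue
                    truth = data.true_indicator
                    for method in methods:
                        try:
                            model, imp = _fit_method(
                                method, data, X_tr, y_tr, n_trees, max_depth, cell_seed
                            )
                            top = top_k_features(imp, min(k_top, base.p))
                            rep_graph = induced_subgraph_metrics(data.graph, top)
                            rows.append(
                                {
                                    **common,
                                    "method": method,
                                    "test_accuracy": float(
                                        np.mean(model.predict(X_te) == y_te)
                                    ),
                                    "auc": roc_auc(imp, truth),
                                    "pr_auc": pr_auc(imp, truth),
                                    "density": rep_graph.density,
                                    "n_components": rep_graph.n_components,
                                    "largest_component": rep_graph.largest_component_size,
                                    "error": "",
                                }
                            )
                        except Exception as exc:
                            rows.append({**common, "method": method, "error": str(exc)})
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation per (p0, n_cores, link, method) cell."""
    metrics = [
        c
        for c in (
            "test_accuracy", "auc", "pr_auc", "density", "n_components", "largest_component"
        )
        if c in results.columns
    ]
    ok = results[results.get("error", "") == ""] if "error" in results.columns else results
    return (
        ok.groupby(["p0", "n_cores", "link", "method"])[metrics]
        .agg(["mean", "std"])
        .reset_index()
    )
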