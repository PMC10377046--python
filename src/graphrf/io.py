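"""Delimited-table I/O and dataset harmonization.

Real studies pair an expression matrix (samples x features) with an interaction
network whose node set rarely matches the measured features. Harmonization
intersects the two, restricts the network to its largest connected component
among surviving features, and reorders expression columns to match the graph,
recording how many features each step dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import FeatureGraph

__all__ = [
    "ExpressionTable",
    "HarmonizedDataset",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "log_transform",
    "harmonize",
]


@dataclass(frozen=True)
class ExpressionTable:
    """A numeric samples x features matrix with identifier rows/columns."""

    samples: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray
    log_transformed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"matrix shape {v.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature identifiers")
        if not np.isfinite(v).all():
            raise ValueError("expression values must be finite")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.features))


def read_expression(
    path: str | Path,
    orientation: Literal["samples-by-features", "features-by-samples"],
    delimiter: str = "\t",
) -> ExpressionTable:
    """Read a delimited expression table with one identifier row and column.

    ``orientation`` must be declared explicitly — near-square matrices make
    guessing unsafe. Non-numeric cells and duplicate feature identifiers are
    reported with their location.
    """
    if orientation not in ("samples-by-features", "features-by-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate identifiers in header: {dup[:5]}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate identifiers {dup[:5]}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().values)[0]
        raise ValueError(
            f"{path}: non-numeric cell at row '{df.index[r]}', column '{df.columns[c]}'"
        )
    if orientation == "features-by-samples":
        bad = bad.T
    return ExpressionTable(
        samples=tuple(str(s) for s in bad.index),
        features=tuple(str(f) for f in bad.columns),
        values=bad.values.astype(np.float64),
    )


def write_expression(t: ExpressionTable, path: str | Path, delimiter: str = "\t") -> None:
    t.to_frame().to_csv(path, sep=delimiter, index_label="sample")


def read_labels(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample, label) table — or a single label column."""
    df = pd.read_csv(path, sep=delimiter, header=0)
    if df.shape[1] == 1:
        return pd.Series(df.iloc[:, 0].values, name=df.columns[0])
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str), name=df.columns[1])


def write_labels(y: Sequence[int], path: str | Path, samples: Sequence[str] | None = None) -> None:
    if samples is None:
        pd.DataFrame({"label": list(y)}).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame({"sample": list(samples), "label": list(y)}).to_csv(
            path, sep="\t", index=False
        )


def log_transform(t: ExpressionTable, offset: float = 1.0) -> ExpressionTable:
    """Entrywise natural log of (value + offset); refuses nonpositive arguments.

    Not idempotent — the ``log_transformed`` flag on the table guards against
    accidental double application (pass a fresh table to re-apply on purpose).
    """
    if t.log_transformed:
        raise ValueError("table is already log-transformed")
    shifted = t.values + offset
    if (shifted <= 0).any():
        rows, cols = np.nonzero(shifted <= 0)
        where = [
            f"({t.samples[r]}, {t.features[c]})" for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"log of nonpositive value at {', '.join(where)}")
    return ExpressionTable(
        samples=t.samples,
        features=t.features,
        values=np.log(shifted),
        log_transformed=True,
    )


@dataclass(frozen=True)
class HarmonizedDataset:
    """Expression restricted to the largest connected component of the network.

    ``expression.features`` and ``graph.labels`` are identical ordered tuples
    and the graph is connected; ``provenance`` records feature drops per step.
    """

    expression: ExpressionTable
    graph: FeatureGraph
    labels: np.ndarray
    provenance: dict[str, int] = field(default_factory=dict)


def harmonize(
    t: ExpressionTable, g: FeatureGraph, labels: Sequence[int] | pd.Series
) -> HarmonizedDataset:
    """Intersect expression features with graph nodes and keep the largest component.

    Steps: (1) drop expression features absent from the graph and graph nodes
    without expression; (2) among surviving nodes, keep only the largest
    connected component of the induced network; (3) reorder expression columns
    to the graph's node order. Idempotent by construction.
    """
    if g.labels is None:
        raise ValueError("graph must carry node labels to harmonize by identifier")
    labels = np.asarray(labels.values if isinstance(labels, pd.Series) else labels)
    if len(labels) != len(t.samples):
        raise ValueError("label count does not match sample count")

    graph_set = set(g.labels)
    shared = [f for f in t.features if f in graph_set]
    if not shared:
        raise ValueError("no overlap between expression features and graph nodes")

    gx = g.to_networkx()
    keep_idx = {g.index_of(f) for f in shared}
    sub = gx.subgraph(keep_idx)
    largest = max(nx.connected_components(sub), key=lambda c: (len(c), -min(c)))
    kept_labels = [g.labels[i] for i in sorted(largest)]

    new_index = {lab: i for i, lab in enumerate(kept_labels)}
    edges = [
        (new_index[g.labels[a]], new_index[g.labels[b]])
        for a, b in g.edges
        if g.labels[a] in new_index and g.labels[b] in new_index
    ]
    new_graph = FeatureGraph.from_edges(len(kept_labels), edges, labels=kept_labels)

    col = {f: j for j, f in enumerate(t.features)}
    values = t.values[:, [col[f] for f in kept_labels]]
    expr = ExpressionTable(
        samples=t.samples,
        features=tuple(kept_labels),
        values=values,
        log_transformed=t.log_transformed,
    )
    provenance = {
        "features_in": len(t.features),
        "dropped_not_in_graph": len(t.features) - len(shared),
        "graph_nodes_without_expression": g.node_count - len(shared),
        "dropped_outside_largest_component": len(shared) - len(kept_labels),
        "features_out": len(kept_labels),
    }
    return HarmonizedDataset(
        expression=expr, graph=new_graph, labels=labels, provenance=provenance
    )
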