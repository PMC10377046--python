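"""Feature-interaction graphs: construction, distances, neighborhoods, sub-graph metrics.

The graph is the substrate of the whole method: features (genes, miRNAs, ...)
are nodes of an undirected simple graph, and both the simulation covariance and
the forest feature pools are defined through shortest-path hop distances on it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "FeatureGraph",
    "SubgraphReport",
    "UNREACHABLE",
    "generate_ba_graph",
    "shortest_path_matrix",
    "k_hop_neighborhood",
    "induced_subgraph_metrics",
    "connected_components",
    "read_edge_list",
    "write_edge_list",
]

#: Sentinel for unreachable node pairs in distance matrices.
UNREACHABLE = np.inf


@dataclass(frozen=True)
class FeatureGraph:
    """Undirected simple graph over feature indices ``0 .. p-1``.

    Parameters
    ----------
    node_count
        Number of features ``p``.
    edges
        Unordered feature-index pairs; each pair is stored once as
        ``(min, max)``. Self-loops and duplicates are rejected.
    labels
        Optional string identifiers aligned to indices (e.g. gene symbols).
    """

    node_count: int
    edges: frozenset[tuple[int, int]]
    labels: tuple[str, ...] | None = None
    _nx: nx.Graph = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        if self.node_count < 1:
            raise ValueError(f"node_count must be positive, got {self.node_count}")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a}")
            if not (0 <= a < self.node_count and 0 <= b < self.node_count):
                raise ValueError(f"edge ({a},{b}) outside [0,{self.node_count})")
            if a > b:
                raise ValueError(f"edge ({a},{b}) not stored as (min,max)")
        if self.labels is not None:
            if len(self.labels) != self.node_count:
                raise ValueError("labels length must equal node_count")
            if len(set(self.labels)) != self.node_count:
                raise ValueError("duplicate node labels")
        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(self.edges)
        object.__setattr__(self, "_nx", g)

    @classmethod
    def from_edges(
        cls,
        node_count: int,
        edges: Iterable[tuple[int, int]],
        labels: Sequence[str] | None = None,
    ) -> "FeatureGraph":
        canon = frozenset((min(a, b), max(a, b)) for a, b in edges)
        return cls(node_count, canon, tuple(labels) if labels is not None else None)

    def to_networkx(self) -> nx.Graph:
        return self._nx.copy()

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Degree of every node as an int array of length ``p``."""
        deg = np.zeros(self.node_count, dtype=np.int64)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def adjacency(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix."""
        if not self.edges:
            return sp.csr_matrix((self.node_count, self.node_count))
        rows, cols = zip(*self.edges)
        rows, cols = np.asarray(rows), np.asarray(cols)
        data = np.ones(2 * len(self.edges), dtype=np.int8)
        return sp.csr_matrix(
            (data, (np.r_[rows, cols], np.r_[cols, rows])),
            shape=(self.node_count, self.node_count),
        )

    def neighbors(self, node: int) -> set[int]:
        return set(self._nx.neighbors(node))

    def is_connected(self) -> bool:
        return nx.is_connected(self._nx)

    def index_of(self, label: str) -> int:
        if self.labels is None:
            raise ValueError("graph has no node labels")
        return self.labels.index(label)


@dataclass(frozen=True)
class SubgraphReport:
    """Topology summary of the sub-graph induced by a selected feature set.

    ``density`` is |E_sub| / (s(s-1)/2) for s >= 2 selected nodes (0.0 for a
    single node). ``avg_distance`` averages shortest-path hops over pairs that
    are connected *within* the induced sub-graph only; disconnected pairs are
    excluded, not counted as infinite. ``avg_distance_largest`` restricts the
    average to pairs inside the largest connected component. Both are NaN when
    no connected pair exists.
    """

    n_selected: int
    n_edges: int
    density: float
    n_components: int
    largest_component_size: int
    avg_distance: float
    avg_distance_largest: float


def generate_ba_graph(
    p: int,
    power: float = 0.5,
    edges_per_new_node: int = 1,
    seed: int | np.random.Generator = 0,
) -> FeatureGraph:
    """Grow a scale-free graph by preferential attachment with kernel degree**power.

    Nodes are added sequentially starting from the edge {0, 1}; each new node
    attaches to ``edges_per_new_node`` distinct existing nodes, drawn with
    probability proportional to ``degree ** power``. ``power=1`` is classical
    linear preferential attachment; ``power=0.5`` (the default) yields a milder
    but still heavy-tailed degree distribution typical of biological networks.
    With ``edges_per_new_node=1`` the result is a tree (hence connected with
    exactly p-1 edges).
    """
    if p < 2:
        raise ValueError(f"p must be >= 2, got {p}")
    if power < 0:
        raise ValueError(f"power must be >= 0, got {power}")
    if edges_per_new_node < 1:
        raise ValueError(f"edges_per_new_node must be >= 1, got {edges_per_new_node}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    deg = np.zeros(p, dtype=np.float64)
    deg[0] = deg[1] = 1.0
    edges: list[tuple[int, int]] = [(0, 1)]
    for t in range(2, p):
        m = min(edges_per_new_node, t)
        w = deg[:t] ** power
        targets: list[int] = []
        for _ in range(m):
            ww = w.copy()
            ww[targets] = 0.0
            total = ww.sum()
            if total <= 0:  # degenerate (cannot happen after the seed edge)
                choices = np.setdiff1d(np.arange(t), targets)
                tgt = int(rng.choice(choices))
            else:
                tgt = int(rng.choice(t, p=ww / total))
            targets.append(tgt)
        for tgt in targets:
            edges.append((min(tgt, t), max(tgt, t)))
            deg[tgt] += 1
            deg[t] += 1
    return FeatureGraph.from_edges(p, edges)


def shortest_path_matrix(g: FeatureGraph) -> np.ndarray:
    """All-pairs unweighted shortest hop counts as a dense ``p x p`` float matrix.

    Unreachable pairs carry :data:`UNREACHABLE` (``inf``); the diagonal is 0 and
    the matrix is symmetric.
    """
    if g.node_count < 1:
        raise ValueError("empty graph")
    D = shortest_path(g.adjacency(), method="D", directed=False, unweighted=True)
    return D


def k_hop_neighborhood(g: FeatureGraph, node: int, k: int) -> set[int]:
    """Nodes within ``k`` hops of ``node``, including ``node`` itself.

    The head node must be part of its own feature pool, so the neighborhood is
    inclusive; ``k=0`` returns the singleton {node}.
    """
    if not (0 <= node < g.node_count):
        raise ValueError(f"node {node} outside [0,{g.node_count})")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return set(nx.single_source_shortest_path_length(g._nx, node, cutoff=k))


def _validate_selection(g: FeatureGraph, selected: Iterable[int]) -> list[int]:
    sel = sorted(set(int(s) for s in selected))
    if not sel:
        raise ValueError("selection must be nonempty")
    if sel[0] < 0 or sel[-1] >= g.node_count:
        raise ValueError("selection contains nodes outside the graph")
    return sel


def connected_components(g: FeatureGraph, selected: Iterable[int]) -> list[set[int]]:
    """Partition of ``selected`` into connected blocks of the induced sub-graph.

    Two selected nodes share a block iff a path using only selected nodes joins
    them. Blocks are returned largest-first (ties by smallest member).
    """
    sel = _validate_selection(g, selected)
    sub = g._nx.subgraph(sel)
    comps = [set(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def induced_subgraph_metrics(g: FeatureGraph, selected: Iterable[int]) -> SubgraphReport:
    """Density, component structure and average hop distances of an induced sub-graph.

    This is the connectivity report used to judge whether a selected feature set
    (e.g. the top-100 most important features) forms a coherent module in the
    interaction network rather than a scattered collection.
    """
    sel = _validate_selection(g, selected)
    sub = g._nx.subgraph(sel)
    s = len(sel)
    n_edges = sub.number_of_edges()
    density = 0.0 if s < 2 else n_edges / (s * (s - 1) / 2)
    comps = [set(c) for c in nx.connected_components(sub)]
    largest = max(comps, key=len)

    dist_sum = 0.0
    n_pairs = 0
    dist_sum_largest = 0.0
    n_pairs_largest = 0
    for comp in comps:
        if len(comp) < 2:
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub.subgraph(comp)))
        for a, b in itertools.combinations(sorted(comp), 2):
            d = lengths[a][b]
            dist_sum += d
            n_pairs += 1
            if comp is largest:
                dist_sum_largest += d
                n_pairs_largest += 1
    return SubgraphReport(
        n_selected=s,
        n_edges=n_edges,
        density=density,
        n_components=len(comps),
        largest_component_size=len(largest),
        avg_distance=dist_sum / n_pairs if n_pairs else float("nan"),
        avg_distance_largest=(
            dist_sum_largest / n_pairs_largest if n_pairs_largest else float("nan")
        ),
    )


def read_edge_list(path: str | Path, delimiter: str | None = None) -> FeatureGraph:
    """Read a two-column edge list (tab- or comma-separated labels, '#' comments).

    Labels are mapped to dense indices in order of first appearance and kept on
    the returned graph; duplicate edges collapse, self-loops are rejected.
    """
    labels: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter is None:
            parts = line.split("\t") if "\t" in line else line.split(",")
        else:
            parts = line.split(delimiter)
        parts = [x.strip() for x in parts if x.strip()]
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        a, b = parts
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-loop on '{a}'")
        for lab in (a, b):
            if lab not in labels:
                labels[lab] = len(labels)
        edges.append((labels[a], labels[b]))
    if not labels:
        raise ValueError(f"{path}: no edges found")
    ordered = sorted(labels, key=labels.get)
    return FeatureGraph.from_edges(len(labels), edges, labels=ordered)


def write_edge_list(g: FeatureGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write the graph as a two-column edge list using labels when present."""
    name = (lambda i: g.labels[i]) if g.labels is not None else str
    lines = [f"{name(a)}{delimiter}{name(b)}" for a, b in sorted(g.edges)]
    Path(path).write_text("\n".join(lines) + "\n")
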