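"""Typical real-data workflow: read files, harmonize with the network, fit.

Writes a tiny synthetic expression table and edge list to a temp directory to
stand in for downloaded files, then runs the same steps a real analysis would:
read, log-transform, harmonize to the network's largest connected component,
and fit the graph forest.
"""

import tempfile
from pathlib import Path

import numpy as np

from graphrf import (
    ExpressionTable,
    GraphRandomForestClassifier,
    harmonize,
    log_transform,
    read_edge_list,
    read_expression,
    simulate_dataset,
    write_expression,
)

tmp = Path(tempfile.mkdtemp())

# stand-in for downloaded files: simulated expression + network with gene names
data = simulate_dataset(p=120, n=100, p0=12, seed=3)
genes = [f"GENE{j}" for j in range(120)]
write_expression(
    ExpressionTable(tuple(f"s{i}" for i in range(100)), tuple(genes),
                    np.exp(data.X)),  # positive "raw" values
    tmp / "expression.tsv",
)
(tmp / "network.tsv").write_text(
    "\n".join(f"{genes[a]}\t{genes[b]}" for a, b in sorted(data.graph.edges)) + "\n"
)

table = read_expression(tmp / "expression.tsv", orientation="samples-by-features")
table = log_transform(table, offset=1.0)
graph = read_edge_list(tmp / "network.tsv")
h = harmonize(table, graph, data.y)
print("harmonization provenance:", h.provenance)

clf = GraphRandomForestClassifier(h.graph, hop=2, n_trees=200, seed=0)
clf.fit(h.expression.values, h.labels)
imp = clf.feature_importances_
top = np.argsort(-imp)[:5]
print("top features:", [h.expression.features[j] for j in top])
# The fitted columns are aligned to the harmonized (connected) network, so the
# reported names can be mapped straight back onto the interaction graph.
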