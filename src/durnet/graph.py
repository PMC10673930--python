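"""Directed-graph characterization of an estimated coupling matrix.

The estimated A-matrix is read as the weighted adjacency matrix of a directed
graph over the nodes, with self-connections dropped (zero diagonal) and a
binary companion obtained by thresholding at numerical zero.  Four node
metrics summarize the architecture: directed clustering coefficient,
betweenness centrality (fraction of shortest paths through the node,
endpoints excluded), in-degree and out-degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: magnitude below which an estimated weight counts as an absent edge
ZERO_TOL = 1e-8


@dataclass
class Graph:
    weighted: np.ndarray  # (n, n), [target, source], zero diagonal
    binary: np.ndarray  # bool
    nodes: list[str]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        n = len(self.nodes)
        for t in range(n):
            for s in range(n):
                if self.binary[t, s]:
                    g.add_edge(self.nodes[s], self.nodes[t],
                               weight=float(self.weighted[t, s]))
        return g


def to_graph(a_matrix: np.ndarray, nodes: list[str] | None = None,
             zero_tol: float = ZERO_TOL) -> Graph:
    """Adjacency construction: zero the diagonal, binarize nonzero entries."""
    a = np.array(a_matrix, dtype=float, copy=True)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency source must be a square matrix")
    np.fill_diagonal(a, 0.0)
    binary = np.abs(a) > zero_tol
    a[~binary] = 0.0
    nodes = nodes or [f"node{i + 1}" for i in range(a.shape[0])]
    return Graph(weighted=a, binary=binary, nodes=list(nodes))


def node_metrics(g: Graph) -> pd.DataFrame:
    """Per-node metrics on the binary directed graph.

    Returns a tidy frame with columns node, clustering_coefficient,
    betweenness_centrality, in_degree, out_degree.  Clustering uses the
    directed-triangle generalization; betweenness is normalized by the number
    of ordered node pairs excluding the node itself.
    """
    G = g.to_networkx()
    cc = nx.clustering(G)
    bc = nx.betweenness_centrality(G, normalized=True)
    rows = [(node,
             float(cc[node]),
             float(bc[node]),
             int(G.in_degree(node)),
             int(G.out_degree(node)))
            for node in g.nodes]
    return pd.DataFrame(rows, columns=["node", "clustering_coefficient",
                                       "betweenness_centrality",
                                       "in_degree", "out_degree"])


def metrics_long(g: Graph) -> pd.DataFrame:
    """Metrics in long form (node, metric, value) for TSV export."""
    wide = node_metrics(g)
    return wide.melt(id_vars="node", var_name="metric", value_name="value")
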