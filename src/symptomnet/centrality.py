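"""Node centrality indices for symptom networks.

Distances between connected nodes are the reciprocal absolute edge
weights (strong conditional associations = short distances).  Three
indices are reported per node:

- strength: sum of absolute incident edge weights,
- closeness: (k-1) / sum of shortest-path distances to the other nodes
  (0 when any node is unreachable),
- betweenness: fractional (Brandes) count of shortest paths through the
  node, unordered pairs counted once.

Each index is also z-standardized across the nodes of one network, which
is how centrality profiles are compared between waves.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import SymptomNetwork

logger = logging.getLogger(__name__)

INDICES = ("strength", "closeness", "betweenness")


def distance_matrix(network: SymptomNetwork) -> np.ndarray:
    """All-pairs shortest-path lengths with edge length 1/|weight|.

    Pairs with no connecting path get ``inf``; the diagonal is 0.
    """
    w = np.abs(network.weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    graph = csr_matrix(lengths)
    return dijkstra(graph, directed=False)


def _graph(network: SymptomNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(network.n_nodes))
    w = network.weights
    for i in range(network.n_nodes):
        for j in range(i + 1, network.n_nodes):
            if w[i, j] != 0:
                g.add_edge(i, j, length=1.0 / abs(w[i, j]))
    return g


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(network: SymptomNetwork) -> pd.DataFrame:
    """Raw and z-standardized strength, closeness and betweenness per node."""
    k = network.n_nodes
    strength = np.abs(network.weights).sum(axis=1)

    d = distance_matrix(network)
    dsum = d.sum(axis=1)  # inf propagates for unreachable partners
    with np.errstate(divide="ignore"):
        closeness = np.where(np.isfinite(dsum) & (dsum > 0), (k - 1) / dsum, 0.0)
    if not np.isfinite(dsum).all():
        logger.warning("disconnected network: closeness set to 0 for affected nodes")

    bet = nx.betweenness_centrality(_graph(network), normalized=False, weight="length")
    betweenness = np.array([bet[i] for i in range(k)])

    table = pd.DataFrame(
        {
            "node": list(network.node_labels),
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
        }
    )
    for index in INDICES:
        table[f"{index}_z"] = _zscore(table[index].to_numpy(dtype=float))
    return table


def centrality_vectors(network: SymptomNetwork) -> dict[str, np.ndarray]:
    """Raw centralities keyed by index name (convenience for stability)."""
    t = centrality_table(network)
    return {index: t[index].to_numpy(dtype=float) for index in INDICES}


def centrality_long(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a centrality table to long ``node,index,raw,z`` format."""
    rows = []
    for index in INDICES:
        for _, r in table.iterrows():
            rows.append(
                {"node": r["node"], "index": index, "raw": r[index], "z": r[f"{index}_z"]}
            )
    return pd.DataFrame(rows)
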