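"""Unregularized partial Spearman correlation networks.

A symptom network is a weighted undirected graph whose nodes are scale
items and whose edge weights are partial Spearman correlations: the rank
correlation between two items after conditioning on all remaining items.
Weights are obtained by inverting the Spearman correlation matrix R
(precision matrix K = R^-1) and standardizing:

    rho_ij = -K_ij / sqrt(K_ii * K_jj)

Global connectivity is the sum of absolute edge weights over the 36
unordered node pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scale import TimepointMatrix

logger = logging.getLogger(__name__)

#: Eigenvalue floor below which a correlation matrix is repaired.
PD_EPS = 1e-8


class DegenerateColumnError(ValueError):
    """A constant item column makes rank correlation undefined."""


class SingularCorrelationError(ValueError):
    """Correlation matrix not repairable to positive definite."""


@dataclass
class SymptomNetwork:
    """Symmetric partial-correlation network over the scale items."""

    node_labels: tuple[str, ...]
    weights: np.ndarray  # (k, k), symmetric, zero diagonal
    n: int | str  # sample size, or "population" for ground truth
    timepoint: str | None = None
    pd_repaired: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.node_labels),) * 2:
            raise ValueError("weights must be square and match node count")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0):
            raise ValueError("diagonal must be zero")
        if np.abs(w).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("weights must lie in [-1, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def spearman_matrix(matrix: TimepointMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations with average ranks for ties.

    Computed as Pearson correlation of column-wise average ranks over the
    (already complete-case) rows.
    """
    x = matrix.values if isinstance(matrix, TimepointMatrix) else np.asarray(matrix)
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows for correlation")
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        idx = int(np.argmax(constant))
        name = (
            matrix.scale.item_labels[idx]
            if isinstance(matrix, TimepointMatrix)
            else f"column {idx}"
        )
        raise DegenerateColumnError(f"constant item: {name}")
    ranks = stats.rankdata(x, axis=0)
    r = np.corrcoef(ranks, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def repair_correlation(r: np.ndarray, eps: float = PD_EPS) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the result re-standardized to
    unit diagonal.  Returns the (possibly untouched) matrix and a flag
    recording whether repair was applied.
    """
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= eps:
        return r, False
    clipped = np.clip(vals, eps, None)
    a = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(a))
    fixed = a / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    logger.warning("correlation matrix repaired to PD (min eig %.2e)", vals.min())
    return fixed, True


def partial_from_correlation(r: np.ndarray) -> tuple[np.ndarray, bool]:
    """Partial correlations from a correlation matrix via precision inversion.

    Returns the partial-correlation matrix (zero diagonal) and a flag
    indicating whether PD repair was needed first.
    """
    r = np.asarray(r, dtype=float)
    if not np.allclose(r, r.T, atol=1e-10) or not np.allclose(np.diag(r), 1.0):
        raise ValueError("input must be symmetric with unit diagonal")
    r, repaired = repair_correlation(r)
    try:
        k = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError("correlation matrix singular") from exc
    d = np.sqrt(np.diag(k))
    p = -k / np.outer(d, d)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    if np.abs(p).max() > 1.0:
        logger.warning("partial correlations clamped to [-1, 1]")
        p = np.clip(p, -1.0, 1.0)
    return p, repaired


def estimate_network(matrix: TimepointMatrix | np.ndarray,
                     node_labels: tuple[str, ...] | None = None,
                     timepoint: str | None = None) -> SymptomNetwork:
    """Estimate the partial Spearman network from a complete-case matrix."""
    r = spearman_matrix(matrix)
    p, repaired = partial_from_correlation(r)
    if isinstance(matrix, TimepointMatrix):
        labels = matrix.scale.item_labels
        n = matrix.n
        tp = matrix.timepoint
    else:
        x = np.asarray(matrix)
        labels = node_labels or tuple(f"item_{i}" for i in range(x.shape[1]))
        n = x.shape[0]
        tp = timepoint
    return SymptomNetwork(
        node_labels=tuple(labels), weights=p, n=n, timepoint=tp, pd_repaired=repaired
    )


def connectivity(network: SymptomNetwork | np.ndarray) -> float:
    """Global strength: sum of absolute edge weights over unordered pairs."""
    w = network.weights if isinstance(network, SymptomNetwork) else np.asarray(network)
    iu = np.triu_indices(w.shape[0], k=1)
    return float(np.abs(w[iu]).sum())


@dataclass
class EdgeList:
    """All unordered edges of a network with a display flag.

    The flag marks edges at or above the display threshold; weights are
    never altered by thresholding (presentation only).
    """

    table: pd.DataFrame = field(repr=False)

    def displayed(self) -> pd.DataFrame:
        return self.table[self.table["displayed"]]


def threshold_edges(network: SymptomNetwork, display_min: float = 0.1) -> EdgeList:
    """Flag edges whose |weight| falls strictly below ``display_min``."""
    if display_min < 0:
        raise ValueError("display_min must be >= 0")
    labels = network.node_labels
    iu = np.triu_indices(network.n_nodes, k=1)
    rows = [
        {
            "node_i": labels[i],
            "node_j": labels[j],
            "weight": float(network.weights[i, j]),
            "displayed": bool(abs(network.weights[i, j]) >= display_min),
        }
        for i, j in zip(*iu)
    ]
    return EdgeList(table=pd.DataFrame(rows))


def edge_vector(network: SymptomNetwork | np.ndarray) -> np.ndarray:
    """Upper-triangle edge weights as a flat vector (i < j order)."""
    w = network.weights if isinstance(network, SymptomNetwork) else np.asarray(network)
    return w[np.triu_indices(w.shape[0], k=1)]


def export_network(network: SymptomNetwork, stem: "str | Path",
                   display_min: float = 0.1) -> list[Path]:
    """Write a network as edge-list CSV, adjacency JSON and GraphML.

    ``stem`` is a path without extension; three sibling files are written.
    """
    import json

    import networkx as nx

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written = []

    edges = threshold_edges(network, display_min).table
    csv_path = stem.with_suffix(".edges.csv")
    edges.to_csv(csv_path, index=False)
    written.append(csv_path)

    json_path = stem.with_suffix(".json")
    payload = {
        "nodes": list(network.node_labels),
        "weights": network.weights.tolist(),
        "n": network.n,
        "timepoint": network.timepoint,
        "pd_repaired": network.pd_repaired,
    }
    json_path.write_text(json.dumps(payload, indent=2))
    written.append(json_path)

    g = nx.Graph(timepoint=str(network.timepoint), n=str(network.n))
    g.add_nodes_from(network.node_labels)
    for _, row in edges.iterrows():
        if row["weight"] != 0:
            g.add_edge(row["node_i"], row["node_j"], weight=float(row["weight"]))
    graphml_path = stem.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    written.append(graphml_path)
    return written
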