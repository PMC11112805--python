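"""Network figures: force-directed layout and edge rendering.

Layout uses the Fruchterman-Reingold algorithm with |weight| as the
attraction weight, so strongly conditionally associated symptoms sit
close together.  The layout computed on one network (conventionally the
first wave) is reused for all later waves of a run to keep figures
visually comparable.  Edges below a display threshold are hidden and
width/saturation scale with |weight| relative to a saturation reference;
thresholding and scaling are presentation only and never touch the
stored weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .network import SymptomNetwork

logger = logging.getLogger(__name__)


@dataclass
class LayoutCoordinates:
    """Node positions in the unit square, reusable across same-node networks."""

    positions: dict[str, tuple[float, float]]
    source_network: str | None = None
    seed: int | None = None


def fr_layout(network: SymptomNetwork, seed: int = 0, iterations: int = 200) -> LayoutCoordinates:
    """Deterministic Fruchterman-Reingold layout rescaled to the unit square."""
    g = nx.Graph()
    g.add_nodes_from(network.node_labels)
    w = np.abs(network.weights)
    for i, a in enumerate(network.node_labels):
        for j in range(i + 1, network.n_nodes):
            if w[i, j] > 0:
                g.add_edge(a, network.node_labels[j], weight=float(w[i, j]))
    pos = nx.spring_layout(g, weight="weight", seed=seed, iterations=iterations)
    xy = np.array([pos[n] for n in network.node_labels], dtype=float)
    span = np.ptp(xy, axis=0)
    span[span == 0] = 1.0
    xy = (xy - xy.min(axis=0)) / span
    positions = {n: (float(x), float(y)) for n, (x, y) in zip(network.node_labels, xy)}
    return LayoutCoordinates(
        positions=positions,
        source_network=str(network.timepoint),
        seed=seed,
    )


def render_network(
    network: SymptomNetwork,
    layout: LayoutCoordinates,
    path: str | Path,
    display_min: float = 0.1,
    scale_max: float | None = None,
    title: str | None = None,
) -> Path:
    """Draw a network to an image file using precomputed coordinates.

    ``scale_max`` is the saturation reference: the edge weight rendered
    at full width/opacity.  Defaults to the observed maximum; a reference
    below the observed maximum clamps at full saturation with a warning.
    """
    missing = set(network.node_labels) - set(layout.positions)
    if missing:
        raise ValueError(f"layout lacks positions for {sorted(missing)}")
    w = network.weights
    obs_max = float(np.abs(w).max(initial=0.0))
    if scale_max is None:
        scale_max = obs_max if obs_max > 0 else 1.0
    elif scale_max < obs_max:
        logger.warning(
            "saturation reference %.3f below observed max %.3f; clamping", scale_max, obs_max
        )

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, a in enumerate(network.node_labels):
        for j in range(i + 1, network.n_nodes):
            weight = w[i, j]
            if abs(weight) < display_min or weight == 0:
                continue
            rel = min(abs(weight) / scale_max, 1.0)
            xa, ya = layout.positions[a]
            xb, yb = layout.positions[network.node_labels[j]]
            color = "tab:blue" if weight > 0 else "tab:red"
            ax.plot([xa, xb], [ya, yb], color=color, linewidth=0.5 + 4.5 * rel,
                    alpha=0.25 + 0.75 * rel, zorder=1)
    for label in network.node_labels:
        x, y = layout.positions[label]
        ax.scatter([x], [y], s=900, c="white", edgecolors="black", zorder=2)
        ax.annotate(label.replace("_", "\n"), (x, y), ha="center", va="center",
                    fontsize=6, zorder=3)
    ax.set_xlim(-0.15, 1.15)
    ax.set_ylim(-0.15, 1.15)
    ax.axis("off")
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
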