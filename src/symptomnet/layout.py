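"""Force-directed layout and figure rendering for the symptom network.

Node positions come from a seeded Fruchterman-Reingold iteration with
|weight|-proportional attraction (networkx's spring layout), rescaled
to the unit box. Edges are styled by sign (blue positive, red
negative) with thickness and color saturation proportional to |w|;
nodes are colored by community. Every figure is accompanied by
machine-readable sidecar tables so the styled network can be
reconstructed without parsing the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .ggm import EDGE_EPS, NetworkModel

#: community color classes (configurable at render time)
DEFAULT_COMMUNITY_COLORS = {"anxiety": "#4C72B0", "depression": "#DD8452"}
POSITIVE_COLOR = "#2166AC"
NEGATIVE_COLOR = "#B2182B"


@dataclass
class LayoutCoordinates:
    coords: pd.DataFrame  # index: node, columns x, y in [-1, 1]
    iterations_used: int
    seed: int


def _graph(model: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(model.node_labels)
    for _, row in model.edge_list().iterrows():
        G.add_edge(row["node_a"], row["node_b"],
                   weight=abs(row["weight"]), signed=row["weight"])
    return G


def fruchterman_reingold(
    model: NetworkModel, seed: int = 0, n_iter: int = 500
) -> LayoutCoordinates:
    """Seeded force-directed node placement, rescaled to [-1, 1]^2."""
    G = _graph(model)
    pos = nx.spring_layout(G, weight="weight", seed=seed,
                           iterations=n_iter, center=(0.0, 0.0), scale=1.0)
    if len(G) == 1:
        pos = {model.node_labels[0]: np.zeros(2)}
    coords = pd.DataFrame(
        {lab: pos[lab] for lab in model.node_labels}, index=["x", "y"]
    ).T
    if not np.isfinite(coords.to_numpy()).all():
        raise RuntimeError("layout produced non-finite coordinates")
    return LayoutCoordinates(coords=coords, iterations_used=n_iter, seed=seed)


def edge_styles(model: NetworkModel) -> pd.DataFrame:
    """Sign class, thickness and saturation per nonzero edge.

    Thickness and saturation scale linearly with |w| relative to the
    largest |w| in the network (monotone in |w| by construction).
    """
    edges = model.edge_list()
    if edges.empty:
        return pd.DataFrame(
            columns=["node_a", "node_b", "weight", "sign_class",
                     "thickness", "saturation"]
        )
    wmax = edges["weight"].abs().max()
    rel = edges["weight"].abs() / wmax
    return edges.assign(
        sign_class=np.where(edges["weight"] > 0, "positive", "negative"),
        thickness=0.5 + 4.5 * rel,
        saturation=0.15 + 0.85 * rel,
    )


def render_network(
    model: NetworkModel,
    coords: LayoutCoordinates,
    out_path: str | Path,
    community_colors: dict[str, str] | None = None,
    formats: tuple[str, ...] = ("svg", "png"),
) -> dict[str, Path]:
    """Write the styled network figure plus node/edge sidecar tables.

    ``out_path`` is the stem; returns the written paths keyed by kind.
    """
    colors = community_colors or DEFAULT_COMMUNITY_COLORS
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    styles = edge_styles(model)
    xy = coords.coords

    with plt.rc_context({"svg.hashsalt": "symptomnet"}):
        fig, ax = plt.subplots(figsize=(7, 7))
        for _, e in styles.iterrows():
            a, b = e["node_a"], e["node_b"]
            color = POSITIVE_COLOR if e["sign_class"] == "positive" else NEGATIVE_COLOR
            ax.plot(
                [xy.loc[a, "x"], xy.loc[b, "x"]],
                [xy.loc[a, "y"], xy.loc[b, "y"]],
                color=color, linewidth=e["thickness"],
                alpha=e["saturation"], zorder=1,
            )
        node_colors = [
            colors.get(model.community_of[lab], "#999999")
            for lab in model.node_labels
        ]
        ax.scatter(xy["x"], xy["y"], s=700, c=node_colors,
                   edgecolors="black", linewidths=0.8, zorder=2)
        for lab in model.node_labels:
            ax.annotate(lab, (xy.loc[lab, "x"], xy.loc[lab, "y"]),
                        ha="center", va="center", fontsize=7, zorder=3)
        ax.set_xlim(-1.2, 1.2)
        ax.set_ylim(-1.2, 1.2)
        ax.set_axis_off()
        written: dict[str, Path] = {}
        for fmt in formats:
            target = out_path.with_suffix(f".{fmt}")
            fig.savefig(target, format=fmt, metadata=(
                {"Date": None} if fmt == "svg" else None
            ))
            written[fmt] = target
        plt.close(fig)

    node_sidecar = xy.copy()
    node_sidecar.insert(0, "node", node_sidecar.index)
    node_sidecar["community"] = [
        model.community_of[lab] for lab in node_sidecar["node"]
    ]
    node_sidecar["color"] = node_colors
    nodes_path = out_path.parent / f"{out_path.name}_nodes.csv"
    node_sidecar.to_csv(nodes_path, index=False)
    edges_path = out_path.parent / f"{out_path.name}_edges.csv"
    styles.to_csv(edges_path, index=False)
    written["nodes"] = nodes_path
    written["edges"] = edges_path
    return written
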