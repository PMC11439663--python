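"""Force-directed (spring-embedded) layout for network composition plots.

Fruchterman-Reingold iteration: attractive forces along edges, repulsive
forces between all node pairs, displacement capped by a linearly cooling
temperature.  Nodes move until the maximum displacement falls below a
small fraction of the layout scale or the iteration budget is spent.
Isolated nodes receive positions too (they are drawn as dots without
lines).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graphs import BinaryGraph

__all__ = ["LayoutCoordinates", "spring_layout", "render_network_plot"]


@dataclass
class LayoutCoordinates:
    positions: dict[int, tuple[float, float]]
    iterations_run: int
    seed: int
    energy_history: np.ndarray | None = None

    def as_array(self) -> np.ndarray:
        n = len(self.positions)
        return np.array([self.positions[i] for i in range(n)])


def _energy(pos: np.ndarray, edges: np.ndarray, k: float) -> float:
    """FR potential: sum d^3/(3k) over edges minus k^2 ln d over pairs."""
    n = len(pos)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, 1)
    d = np.maximum(dist[iu], 1e-9)
    rep = -(k**2) * np.log(d).sum()
    att = 0.0
    if len(edges):
        de = np.maximum(dist[edges[:, 0], edges[:, 1]], 1e-9)
        att = (de**3).sum() / (3 * k)
    return float(att + rep)


def spring_layout(
    g: BinaryGraph,
    seed: int = 0,
    iterations: int = 500,
    tol: float = 1e-4,
    track_energy: bool = False,
) -> LayoutCoordinates:
    """Seeded Fruchterman-Reingold layout with displacement early stop.

    Optimal-distance constant k = 1/sqrt(n); temperature cools linearly to
    zero over the iteration budget; the loop stops early once the largest
    step is below ``tol`` times the layout scale.
    """
    n = g.n_nodes
    if n < 1:
        raise ValueError("layout needs at least 1 node")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.5, 0.5, size=(n, 2))
    if n == 1:
        return LayoutCoordinates({0: (float(pos[0, 0]), float(pos[0, 1]))}, 0, seed)
    edges = np.array(g.edge_list(), dtype=int).reshape(-1, 2)
    k = 1.0 / np.sqrt(n)
    t0 = 0.1
    energies = [] if track_energy else None
    it_run = 0
    for it in range(iterations):
        t = t0 * (1 - it / iterations)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion k^2/d between all pairs
        disp = (diff / dist[..., None] * (k**2 / dist)[..., None]).sum(axis=1)
        # attraction d^2/k along edges
        if len(edges):
            ev = pos[edges[:, 0]] - pos[edges[:, 1]]
            ed = np.maximum(np.sqrt((ev**2).sum(-1)), 1e-9)
            f = (ev / ed[:, None]) * (ed**2 / k)[:, None]
            np.add.at(disp, edges[:, 0], -f)
            np.add.at(disp, edges[:, 1], f)
        length = np.maximum(np.sqrt((disp**2).sum(-1)), 1e-12)
        step = disp / length[:, None] * np.minimum(length, t)[:, None]
        pos = pos + step
        it_run = it + 1
        if energies is not None:
            energies.append(_energy(pos, edges, k))
        scale = max(pos.max(0).max() - pos.min(0).min(), 1e-9)
        if np.max(np.sqrt((step**2).sum(-1))) < tol * scale:
            break
    return LayoutCoordinates(
        {i: (float(pos[i, 0]), float(pos[i, 1])) for i in range(n)},
        it_run,
        seed,
        np.array(energies) if energies is not None else None,
    )


def render_network_plot(
    g: BinaryGraph,
    layout: LayoutCoordinates,
    partition=None,
    out: str | Path = "network.svg",
    density: float | None = None,
    node_size: float = 20.0,
) -> Path:
    """Write a figure with nodes colored by canonical network.

    Edges are drawn between connected nodes; the density used for
    thresholding is recorded in the caption line.  SVG output is written
    without a timestamp so identical inputs give identical bytes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = g.n_nodes
    if any(i not in layout.positions for i in range(n)):
        raise ValueError("layout does not cover every node of the graph")
    if partition is not None:
        labels = [partition.assignment.get(i) for i in range(n)]
        unknown = [g.node_labels[i] for i, l in enumerate(labels) if l is None]
        if unknown:
            raise ValueError(f"nodes without a network label: {unknown}")
        palette = {}
        cmap = plt.get_cmap("tab10")
        for l in labels:
            if l not in palette:
                palette[l] = cmap(len(palette) % 10)
        colors = [palette[l] for l in labels]
    else:
        colors = ["#1f77b4"] * n
        palette = {}
    xy = layout.as_array()
    fig, ax = plt.subplots(figsize=(6, 6))
    for i, j in g.edge_list():
        ax.plot(
            [xy[i, 0], xy[j, 0]], [xy[i, 1], xy[j, 1]],
            color="0.75", lw=0.5, zorder=1,
        )
    ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=node_size, zorder=2)
    if palette:
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=c, label=l)
            for l, c in palette.items()
        ]
        ax.legend(handles=handles, fontsize=7, loc="upper right")
    caption = "spring-embedded layout"
    if density is not None:
        caption += f" (network density {density})"
    ax.set_title(caption, fontsize=9)
    ax.set_axis_off()
    out = Path(out)
    if out.suffix.lower() == ".svg":
        # fixed hashsalt + no Date metadata => byte-identical reruns
        with matplotlib.rc_context({"svg.hashsalt": "pscdkit"}):
            fig.savefig(out, metadata={"Date": None})
    else:
        fig.savefig(out)
    plt.close(fig)
    return out
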