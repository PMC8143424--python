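"""Binned state-space densities, neighbourhood smoothing, drift quivers, figures.

Order-parameter points are binned onto an equal-width 2-D grid (50 x 50 by
default; 60 bins for speed/area axes and 140 for the entropy axis when those
variables are plotted), smoothed with a 3 x 3 neighbourhood mean, and drawn as
heat maps with the collective-state regions overlaid as red broken lines.
Transition segments additionally carry a per-bin mean-drift vector field
("where does the group move next in state space from here"), drawn as quivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import json

import matplotlib.pyplot as plt
import numpy as np
from scipy.ndimage import convolve

from .states import DEFAULT_THRESHOLDS, StateThresholds

#: default bin counts per axis for the paper-style figures
BINS_PM = 50
BINS_SPEED_AREA = 60
BINS_ENTROPY = 140


@dataclass
class DensityGrid:
    """Equal-width 2-D histogram with a 3x3-smoothed companion."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # raw counts, shape (nx, ny)
    smoothed: np.ndarray = None
    n_out_of_domain: int = 0
    xlabel: str = "x"
    ylabel: str = "y"
    drift: tuple | None = None  # (U, V) per-bin mean drift, NaN where unoccupied
    meta: dict = field(default_factory=dict)

    @property
    def frequency(self) -> np.ndarray:
        """Smoothed counts scaled to relative frequency (sum of raw counts = 1)."""
        total = self.counts.sum()
        return self.smoothed / total if total > 0 else self.smoothed

    def save(self, stem) -> None:
        """Write the grid as TSV matrices plus JSON edge metadata."""
        stem = Path(stem)
        np.savetxt(stem.with_suffix(".counts.tsv"), self.counts, delimiter="\t", fmt="%g")
        np.savetxt(stem.with_suffix(".smoothed.tsv"), self.smoothed, delimiter="\t", fmt="%g")
        meta = {
            "x_edges": self.x_edges.tolist(),
            "y_edges": self.y_edges.tolist(),
            "xlabel": self.xlabel,
            "ylabel": self.ylabel,
            "n_out_of_domain": self.n_out_of_domain,
        }
        stem.with_suffix(".meta.json").write_text(json.dumps(meta))


def bin_density(
    points: np.ndarray,
    nx: int = BINS_PM,
    ny: int = BINS_PM,
    domain: tuple = ((0.0, 1.0), (0.0, 1.0)),
    xlabel: str = "x",
    ylabel: str = "y",
) -> DensityGrid:
    """Histogram (x, y) points onto an nx x ny grid over a finite domain.

    Bins are half-open with the topmost/rightmost edge closed; points outside
    the domain are counted in ``n_out_of_domain``, never binned.  NaN pairs
    are treated as out of domain.
    """
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 bins per axis")
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("no points to bin")
    finite = np.all(np.isfinite(points), axis=1)
    counts, x_edges, y_edges = np.histogram2d(
        points[finite, 0], points[finite, 1], bins=[nx, ny], range=domain
    )
    grid = DensityGrid(
        x_edges, y_edges, counts,
        n_out_of_domain=int(len(points) - counts.sum()),
        xlabel=xlabel, ylabel=ylabel,
    )
    grid.smoothed = smooth_grid(counts)
    return grid


def smooth_grid(counts: np.ndarray) -> np.ndarray:
    """3x3 neighbourhood mean; border cells average over existing neighbours only."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("grid must be at least 2x2")
    kernel = np.ones((3, 3))
    num = convolve(counts, kernel, mode="constant", cval=0.0)
    den = convolve(np.ones_like(counts), kernel, mode="constant", cval=0.0)
    return num / den


def mean_drift(segments: list, grid: DensityGrid) -> tuple:
    """Per-bin mean next-step displacement in state space, pooled over segments.

    Each segment is an ordered (n, 2) array; every sample but the last
    contributes the vector to its successor, assigned to the bin holding the
    sample.  Bins with no samples get NaN (no arrow).
    """
    nx, ny = len(grid.x_edges) - 1, len(grid.y_edges) - 1
    sum_uv = np.zeros((nx, ny, 2))
    n = np.zeros((nx, ny))
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if len(seg) < 2:
            continue
        cur, nxt = seg[:-1], seg[1:]
        ok = np.all(np.isfinite(cur), axis=1) & np.all(np.isfinite(nxt), axis=1)
        cur, delta = cur[ok], (nxt - cur)[ok]
        ix = np.searchsorted(grid.x_edges, cur[:, 0], side="right") - 1
        iy = np.searchsorted(grid.y_edges, cur[:, 1], side="right") - 1
        ix = np.where(np.isclose(cur[:, 0], grid.x_edges[-1]), nx - 1, ix)
        iy = np.where(np.isclose(cur[:, 1], grid.y_edges[-1]), ny - 1, iy)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(sum_uv, (ix[inside], iy[inside]), delta[inside])
        np.add.at(n, (ix[inside], iy[inside]), 1)
    with np.errstate(invalid="ignore"):
        uv = np.where(n[..., None] > 0, sum_uv / np.maximum(n, 1)[..., None], np.nan)
    grid.drift = (uv[..., 0], uv[..., 1])
    return grid.drift


# ---------------------------------------------------------------------------
# rendering


def _overlay_state_regions(ax, th: StateThresholds = DEFAULT_THRESHOLDS) -> None:
    """Red broken-line state-region boundaries on a (p, m) axes."""
    style = dict(color="red", linestyle="--", linewidth=1.2)
    # polar: p > hi, m < lo
    ax.plot([th.hi, th.hi], [0, th.lo], **style)
    ax.plot([th.hi, 1.0], [th.lo, th.lo], **style)
    # swarm: p < lo, m < lo
    ax.plot([th.lo, th.lo], [0, th.lo], **style)
    ax.plot([0.0, th.lo], [th.lo, th.lo], **style)
    # milling: p < lo, m > hi
    ax.plot([th.lo, th.lo], [th.hi, 1.0], **style)
    ax.plot([0.0, th.lo], [th.hi, th.hi], **style)


def plot_density(
    grid: DensityGrid,
    path=None,
    state_regions: bool = False,
    quiver: bool = False,
    title: str | None = None,
    cmap: str = "viridis",
):
    """Heat map of a density grid, optional state-region overlay and drift quivers."""
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, grid.frequency.T, cmap=cmap)
    fig.colorbar(mesh, ax=ax, label="relative frequency")
    if state_regions:
        _overlay_state_regions(ax)
    if quiver and grid.drift is not None:
        cx = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        cy = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        U, V = grid.drift
        ok = np.isfinite(U)
        ax.quiver(X[ok], Y[ok], U[ok], V[ok], color="white", width=0.003, scale=1.5)
    ax.set_xlabel(grid.xlabel)
    ax.set_ylabel(grid.ylabel)
    if title:
        ax.set_title(title)
    return _finish(fig, path)


def plot_phase_graph(graph, path=None):
    """Phase-transition digraph with cumulative minutes and edge proportions."""
    import networkx as nx

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    pos = nx.circular_layout(graph)
    colors = {"attacking": "#4477AA", "defending": "#66AA55", "out_of_play": "#999999"}
    nx.draw_networkx_nodes(
        graph, pos, ax=ax, node_size=2600,
        node_color=[colors.get(n, "#CCCCCC") for n in graph.nodes],
    )
    labels = {
        n: f"{n}\n{graph.nodes[n]['minutes']:.1f} min" for n in graph.nodes
    }
    nx.draw_networkx_labels(graph, pos, labels, ax=ax, font_size=8)
    nx.draw_networkx_edges(
        graph, pos, ax=ax, edge_color="red", connectionstyle="arc3,rad=0.15",
        node_size=2600, arrowsize=16,
    )
    edge_labels = {e: f"{graph.edges[e]['weight']:.2f}" for e in graph.edges}
    nx.draw_networkx_edge_labels(graph, pos, edge_labels, ax=ax, font_size=8)
    ax.set_axis_off()
    return _finish(fig, path)


def plot_survival(curves: dict, path=None, title: str | None = None):
    """Step-plot of Kaplan-Meier curves, one per labelled group."""
    fig, ax = plt.subplots(figsize=(5.2, 4.0))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{label} (n={curve.n_samples})")
    ax.set_xlabel("duration (s)")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return _finish(fig, path)


def plot_duration_kde(curves: dict, path=None):
    """Kernel-density curves of play-segment durations, one per phase."""
    fig, ax = plt.subplots(figsize=(5.2, 4.0))
    for label, (grid, density) in curves.items():
        ax.plot(grid, density, label=label)
    ax.set_xlabel("segment duration (s)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return _finish(fig, path)


_STATE_COLORS = {"polar": "#3366CC", "transitional": "#33AA33", "swarm": "#CC3333",
                 "milling": "#AA33AA"}


def plot_transition_exemplar(series, ops, labels, segment, path=None):
    """Exemplar transition: position traces coloured by state, centroid trace,
    and p, v, H time-series panels over one transition segment."""
    sl = slice(segment.start_idx, segment.end_idx)
    t = series.timestamps[sl]
    lab = labels[sl]
    fig, axes = plt.subplots(1, 5, figsize=(18, 3.4))
    ax_pos, ax_cen, ax_p, ax_v, ax_h = axes

    cen = series.centroids()[sl]
    # colour by maximal constant-state chunks
    chunk_start = 0
    for k in range(1, len(lab) + 1):
        if k == len(lab) or lab[k] != lab[chunk_start]:
            c = _STATE_COLORS.get(lab[chunk_start], "#888888")
            idx = slice(segment.start_idx + chunk_start, segment.start_idx + k)
            for j in range(series.n_players):
                ax_pos.plot(series.positions[idx, j, 0], series.positions[idx, j, 1],
                            color=c, linewidth=0.8)
            ax_cen.plot(cen[chunk_start:k, 0], cen[chunk_start:k, 1], color=c,
                        linewidth=1.6)
            chunk_start = k
    ax_pos.set_title("player traces")
    ax_cen.set_title("centroid")
    for ax in (ax_pos, ax_cen):
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_aspect("equal", adjustable="datalim")
    for ax, y, name in ((ax_p, ops.p[sl], "p_group"),
                        (ax_v, ops.v[sl], "v_group (m/s)"),
                        (ax_h, ops.H[sl], "H_group (bits)")):
        ax.plot(t - t[0], y, color="black", linewidth=1.0)
        ax.set_xlabel("time (s)")
        ax.set_title(name)
    fig.tight_layout()
    return _finish(fig, path)


def _finish(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig
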