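"""Figure rendering: connectograms and spatiotemporal heatmaps.

Figures are drawn directly on Agg canvases (no pyplot state), which keeps
headless runs and repeated renders deterministic.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .dfc import ConnectivityConsensus
from .spatiotemporal import DifferenceMap, SpatiotemporalMap

logger = logging.getLogger(__name__)

POSITIVE_COLOR = "#2060c0"   # positive correlation
NEGATIVE_COLOR = "#c03020"   # negative correlation


def _save(fig: Figure, out_path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(out_path, dpi=120, metadata={"Software": None}
                if out_path.suffix == ".png" else None)
    return out_path


def _circular_positions(roi_ids) -> dict:
    graph = nx.Graph()
    graph.add_nodes_from(roi_ids)
    return nx.circular_layout(graph, scale=1.0)


def render_connectogram(consensus: ConnectivityConsensus, out_path,
                        title: str | None = None) -> Path:
    """Circular consensus graph: width = subject count, color = sign."""
    pos = _circular_positions(consensus.roi_ids)
    fig = Figure(figsize=(7, 7))
    ax = fig.add_subplot(111)
    retained = consensus.retained
    if retained.empty:
        warnings.warn("consensus graph is empty; rendering a blank figure")
    n_max = max(int(retained["n_subjects"].max()), consensus.min_subjects) \
        if not retained.empty else consensus.min_subjects
    for _, edge in retained.iterrows():
        (x0, y0), (x1, y1) = pos[edge["roi_a"]], pos[edge["roi_b"]]
        frac = ((edge["n_subjects"] - consensus.min_subjects)
                / max(n_max - consensus.min_subjects, 1))
        ax.plot([x0, x1], [y0, y1],
                lw=0.8 + 3.2 * frac,
                color=POSITIVE_COLOR if edge["sign"] == "+" else NEGATIVE_COLOR,
                alpha=0.85, zorder=1)
    xs = [pos[r][0] for r in consensus.roi_ids]
    ys = [pos[r][1] for r in consensus.roi_ids]
    ax.scatter(xs, ys, s=14, color="0.2", zorder=2)
    for roi in consensus.roi_ids:
        x, y = pos[roi]
        ax.annotate(str(roi), (1.08 * x, 1.08 * y), fontsize=5,
                    ha="center", va="center")
    ax.set_title(title or f"Consensus connectivity ({consensus.epoch}, "
                          f">= {consensus.min_subjects} subjects)")
    ax.set_aspect("equal")
    ax.axis("off")
    return _save(fig, out_path)


def render_connectivity_difference(difference, roi_ids, out_path,
                                   title: str | None = None) -> Path:
    """Start-only edges thin, end-only edges thick (one color per class)."""
    pos = _circular_positions(roi_ids)
    fig = Figure(figsize=(7, 7))
    ax = fig.add_subplot(111)
    styles = {"start_only": dict(lw=0.8, color="0.45"),
              "end_only": dict(lw=2.8, color="0.1")}
    for _, edge in difference.iterrows():
        if edge["category"] not in styles:
            continue
        (x0, y0), (x1, y1) = pos[edge["roi_a"]], pos[edge["roi_b"]]
        ax.plot([x0, x1], [y0, y1], alpha=0.9, zorder=1,
                **styles[edge["category"]])
    xs = [pos[r][0] for r in roi_ids]
    ys = [pos[r][1] for r in roi_ids]
    ax.scatter(xs, ys, s=14, color="0.2", zorder=2)
    ax.set_title(title or "Connectivity difference (thin = start only, "
                          "thick = end only)")
    ax.set_aspect("equal")
    ax.axis("off")
    return _save(fig, out_path)


def render_spatiotemporal(map_, out_path, title: str | None = None) -> Path:
    """Heatmap of the consensus map (or diverging map for differences).

    The x axis is percent of decision time (0% = stimulus onset, 100% =
    button press); color is the number of agreeing subjects. Cells below
    threshold are background. Difference maps use a diverging palette
    (yes-dominant vs no-dominant).
    """
    if isinstance(map_, SpatiotemporalMap):
        values = np.where(map_.counts >= map_.min_subjects,
                          map_.counts.astype(float), np.nan)
        cmap, vmin, vmax = "viridis", 0, max(map_.n_subjects, 1)
        label = "subjects"
        default_title = f"Spatiotemporal consensus ({map_.condition})"
    elif isinstance(map_, DifferenceMap):
        values = np.where(map_.retained, map_.diff.astype(float), np.nan)
        bound = max(int(np.nanmax(np.abs(map_.diff))) if map_.diff.size else 1, 1)
        cmap, vmin, vmax = "coolwarm", -bound, bound
        label = "N_yes - N_no"
        default_title = "Yes vs no consensus difference"
    else:
        raise TypeError("expected a SpatiotemporalMap or DifferenceMap")
    if np.all(np.isnan(values)):
        warnings.warn("thresholded map is empty; rendering background only")
    starts = map_.window_starts
    step = starts[1] - starts[0] if len(starts) > 1 else 5.0
    fig = Figure(figsize=(8, max(3.0, 0.09 * len(map_.roi_ids))))
    ax = fig.add_subplot(111)
    mesh = ax.imshow(values, aspect="auto", interpolation="nearest",
                     cmap=cmap, vmin=vmin, vmax=vmax,
                     extent=(float(starts[0]), float(starts[-1] + step),
                             len(map_.roi_ids) - 0.5, -0.5))
    ax.set_xlim(0, 100)
    ax.set_xlabel("normalized decision time (%)")
    ax.set_ylabel("ROI")
    tick_every = max(1, len(map_.roi_ids) // 30)
    ax.set_yticks(np.arange(0, len(map_.roi_ids), tick_every))
    ax.set_yticklabels([str(map_.roi_ids[i])
                        for i in range(0, len(map_.roi_ids), tick_every)],
                       fontsize=5)
    fig.colorbar(mesh, ax=ax, label=label)
    ax.set_title(title or default_title)
    return _save(fig, out_path)
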