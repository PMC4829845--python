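"""Plotting: spherical scatter, spherical histogram, landscape, composition.

All panels draw the chromaticity octant as a flat (theta, phi) projection,
the same coordinates the grid uses; figures are deterministic given their
inputs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LogNorm

from .colorspace import ChromaticityGrid, ColorEvents
from .landscape import UNASSIGNED, ChromaticLandscape

__all__ = [
    "plot_scatter",
    "plot_histogram",
    "plot_landscape",
    "plot_composition",
    "render_plots",
]


def _octant_axes(ax):
    ax.set_xlim(0, 90)
    ax.set_ylim(0, 90)
    ax.set_xlabel("azimuth Θ (deg)  [R → G]")
    ax.set_ylabel("elevation Φ (deg)  [→ B]")
    ax.set_aspect("equal")


def _event_colors(events: ColorEvents) -> np.ndarray:
    rgb = np.column_stack([events.r, events.g, events.b])
    peak = rgb.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return np.clip(rgb / peak, 0, 1)


def plot_scatter(events: ColorEvents, ax=None, max_points: int = 50_000, seed: int = 0):
    """Chromaticity scatter of events, colored by their own RGB ratios."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ok = events.defined
    idx = np.flatnonzero(ok)
    if idx.size > max_points:
        idx = np.random.default_rng(seed).choice(idx, max_points, replace=False)
    ax.scatter(
        events.theta[idx], events.phi[idx], s=2,
        c=_event_colors(events.subset(idx)), linewidths=0,
    )
    _octant_axes(ax)
    ax.set_title(f"spherical scatter (n={ok.sum()})")
    return ax


def plot_histogram(grid: ChromaticityGrid, ax=None, log: bool = True):
    """Spherical histogram: adjusted cell count per grid element."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    counts = grid.counts.T  # imshow rows = phi
    norm = LogNorm(vmin=max(counts[counts > 0].min(), 1e-3), vmax=counts.max()) \
        if log and counts.max() > 0 else None
    im = ax.imshow(
        counts, origin="lower", extent=(0, 90, 0, 90), cmap="viridis",
        norm=norm, interpolation="nearest",
    )
    plt.colorbar(im, ax=ax, label="adjusted cell count")
    _octant_axes(ax)
    ax.set_title(f"spherical histogram ({grid.resolution_deg}° grid)")
    return ax


def plot_landscape(landscape: ChromaticLandscape, ax=None):
    """Clone contours, modes and UNASSIGNED shading of the assignment map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    res = landscape.resolution_deg
    extent = (0, 90, 0, 90)
    unassigned = (landscape.assignment < 0).T
    covered = np.zeros_like(unassigned)
    for m in landscape.spread_masks.values():
        covered |= m.T
    shade = np.where(unassigned & covered, 1.0, np.nan)
    ax.imshow(
        shade, origin="lower", extent=extent, cmap="Greys",
        vmin=0, vmax=2, interpolation="nearest",
    )
    cmap = plt.get_cmap("tab20")
    for k, c in enumerate(landscape.clone_ids):
        color = cmap(k % 20)
        ax.contour(
            landscape.spread_masks[c].T.astype(float),
            levels=[0.5], extent=extent, colors=[color], linewidths=1.0,
        )
        m = landscape.modes[c]
        ax.plot(m.theta, m.phi, "+", color=color, markersize=8)
        ax.annotate(c, (m.theta, m.phi), fontsize=7, color=color,
                    xytext=(3, 3), textcoords="offset points")
    _octant_axes(ax)
    ax.set_title(
        f"chromatic landscape ({len(landscape.clone_ids)} clones, "
        f"{100 * landscape.landscape_fraction:g}% contours, "
        f"{landscape.policy} policy; grey = {UNASSIGNED})"
    )
    return ax


def plot_composition(timeseries, ax=None):
    """Stacked clone-frequency trajectories (tidy track() table in)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    wide = timeseries.pivot(index="timepoint", columns="clone_id", values="mean_pct")
    order = [c for c in wide.columns if c != UNASSIGNED] + (
        [UNASSIGNED] if UNASSIGNED in wide.columns else []
    )
    wide = wide[order]
    ax.stackplot(wide.index, wide.T.to_numpy(), labels=wide.columns)
    ax.set_xlabel("timepoint")
    ax.set_ylabel("clonal frequency (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=6, ncol=2, loc="center left", bbox_to_anchor=(1, 0.5))
    return ax


def render_plots(obj, out_path):
    """Render any supported object (grid, events, landscape, composition
    table) to a figure file; dispatches on type."""
    import pandas as pd

    if isinstance(obj, ChromaticityGrid):
        ax = plot_histogram(obj)
    elif isinstance(obj, ColorEvents):
        ax = plot_scatter(obj)
    elif isinstance(obj, ChromaticLandscape):
        ax = plot_landscape(obj)
    elif isinstance(obj, pd.DataFrame):
        ax = plot_composition(obj)
    else:
        raise TypeError(f"cannot plot object of type {type(obj).__name__}")
    fig = ax.get_figure()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path
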