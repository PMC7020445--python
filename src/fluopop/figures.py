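"""Figure rendering: raster, dF/F0 heat map, feature scatter, stacked
bars of class percentages, and box plots with 10-90% whiskers.

All functions take an axes (or create one), draw, and return the figure;
empty inputs produce a placeholder panel with a warning annotation rather
than an error so batch reports never die on a degenerate condition.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless batch rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .population import CLASS_ORDER, ActivityClass, SubpopulationProfile
from .traces import SpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "plot_raster",
    "plot_heatmap",
    "plot_feature_scatter",
    "plot_stacked_bars",
    "plot_box",
    "render_figures",
]


def _placeholder(ax, message: str):
    logger.warning("empty input for figure: %s", message)
    ax.text(0.5, 0.5, f"no data: {message}", ha="center", va="center",
            transform=ax.transAxes)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax.figure


def plot_raster(spike_trains: Sequence[SpikeTrain], frame_interval: float = 10.0, ax=None):
    """Cells x time raster, one mark per detected spike."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if not spike_trains:
        return _placeholder(ax, "no spike trains")
    for row, st in enumerate(spike_trains):
        t = st.spike_frames * frame_interval
        ax.vlines(t, row + 0.6, row + 1.4, color="k", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    ax.set_ylim(0.5, len(spike_trains) + 0.5)
    return ax.figure


def plot_heatmap(dff: np.ndarray, frame_interval: float = 10.0, ax=None):
    """Cells x frames dF/F0 heat map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if dff.size == 0:
        return _placeholder(ax, "no traces")
    n_frames = dff.shape[1]
    im = ax.imshow(
        dff, aspect="auto", cmap="viridis", interpolation="nearest",
        extent=(0, n_frames * frame_interval, dff.shape[0] + 0.5, 0.5),
    )
    ax.figure.colorbar(im, ax=ax, label="dF/F0")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    return ax.figure


def plot_feature_scatter(
    features: pd.DataFrame, classes: Sequence[ActivityClass] | None = None, ax=None
):
    """Spike count vs Ca2+max, colored red/green/black/cyan by class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if features.empty:
        return _placeholder(ax, "no features")
    if classes is None and "class" in features.columns:
        classes = [ActivityClass(c) for c in features["class"]]
    if classes is None:
        ax.scatter(features["spike_count"], features["ca_max"], s=15, c="gray")
    else:
        for cls in CLASS_ORDER:
            sel = [i for i, c in enumerate(classes) if c == cls]
            if sel:
                ax.scatter(
                    features["spike_count"].iloc[sel], features["ca_max"].iloc[sel],
                    s=15, c=cls.color, label=cls.value,
                )
        ax.legend(fontsize=8)
    ax.set_xlabel("Ca$^{2+}$ spike count / 600 s")
    ax.set_ylabel("Ca$^{2+}_{max}$ (dF/F0)")
    return ax.figure


def plot_stacked_bars(
    profiles_by_condition: Mapping[str, Sequence[SubpopulationProfile]], ax=None
):
    """Stacked bars of mean class percentages per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if not profiles_by_condition:
        return _placeholder(ax, "no profiles")
    conditions = list(profiles_by_condition)
    bottoms = np.zeros(len(conditions))
    for cls in CLASS_ORDER:
        heights = [
            float(np.mean([p.percent[cls] for p in profiles_by_condition[c]]))
            for c in conditions
        ]
        ax.bar(conditions, heights, bottom=bottoms, color=cls.color,
               edgecolor="white", label=cls.value)
        bottoms += heights
    ax.set_ylabel("% of cells")
    ax.legend(fontsize=8, bbox_to_anchor=(1.02, 1), loc="upper left")
    return ax.figure


def plot_box(samples: Mapping[str, Sequence[float]], ylabel: str = "", ax=None):
    """Box plots: median, interquartile box, whiskers at the 10th/90th
    percentiles."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    samples = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if not samples or all(v.size == 0 for v in samples.values()):
        return _placeholder(ax, "no samples")
    ax.boxplot(
        list(samples.values()), tick_labels=list(samples.keys()), whis=(10, 90),
        showfliers=False,
    )
    ax.set_ylabel(ylabel)
    return ax.figure


def render_figures(results: dict, outdir) -> list[str]:
    """Render every figure whose inputs are present in ``results``.

    Recognized keys: ``spike_trains_by_condition``, ``dff_by_condition``,
    ``features_by_condition`` (tables with a "class" column),
    ``profiles_by_condition``, ``frame_interval``. Returns the list of
    files written (PNG).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dt = results.get("frame_interval", 10.0)
    written = []

    def _save(fig, name):
        path = outdir / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))

    for cond, trains in results.get("spike_trains_by_condition", {}).items():
        _save(plot_raster(trains, dt), f"raster_{cond}.png")
    for cond, dff in results.get("dff_by_condition", {}).items():
        _save(plot_heatmap(np.asarray(dff), dt), f"heatmap_{cond}.png")
    for cond, feats in results.get("features_by_condition", {}).items():
        _save(plot_feature_scatter(feats), f"scatter_{cond}.png")
    profiles = results.get("profiles_by_condition")
    if profiles:
        _save(plot_stacked_bars(profiles), "stacked_bars.png")
    for name, samples in results.get("box_samples", {}).items():
        _save(plot_box(samples, ylabel=name), f"box_{name}.png")
    return written
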