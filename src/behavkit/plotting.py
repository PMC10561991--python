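"""Static rendering of the analysis outputs.

Thin matplotlib/seaborn wrappers over the plot-ready tables and
matrices produced elsewhere in the package: specimen-by-time heatmaps,
population sleep profiles with their bootstrap ribbons, double-plotted
actograms, periodograms with significance lines, stage-occupancy
curves, and SVM decision surfaces.  Every function takes an optional
``ax`` and returns it, so figures compose the usual matplotlib way.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

__all__ = [
    "plot_heatmap",
    "plot_sleep_profile",
    "plot_actogram",
    "plot_periodogram",
    "plot_state_occupancy",
    "plot_decision_surface",
]


def _ensure_ax(ax):
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_heatmap(matrix: pd.DataFrame, ax=None, cmap="viridis"):
    """Specimen-by-time activity heatmap (rows in metadata order)."""
    ax = _ensure_ax(ax)
    sns.heatmap(matrix, ax=ax, cmap=cmap,
                cbar_kws={"label": "activity"}, xticklabels=False)
    ax.set_xlabel("time bin")
    ax.set_ylabel("specimen")
    return ax


def plot_sleep_profile(profile: pd.DataFrame, ax=None):
    """Mean fraction asleep by ZT with the bootstrap CI ribbon."""
    ax = _ensure_ax(ax)
    for grp, sub in profile.groupby("group"):
        sub = sub.sort_values("zt_bin")
        ax.plot(sub["zt_bin"], sub["mean_fraction_asleep"], label=str(grp))
        ax.fill_between(sub["zt_bin"], sub["ci_low"], sub["ci_high"], alpha=0.25)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel("fraction asleep")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_actogram(matrix: np.ndarray, ax=None, bin_s: float = 1800.0):
    """Double-plotted actogram raster (one row per day)."""
    ax = _ensure_ax(ax)
    ax.imshow(matrix, aspect="auto", cmap="Greys", interpolation="nearest")
    n_cols = matrix.shape[1]
    ax.set_xticks(np.linspace(0, n_cols, 5))
    ax.set_xticklabels([f"{h:.0f}" for h in
                        np.linspace(0, n_cols * bin_s / 3600.0, 5)])
    ax.set_xlabel("time of day (h, double plotted)")
    ax.set_ylabel("day")
    return ax


def plot_periodogram(result, ax=None):
    """Q curve with its significance line."""
    ax = _ensure_ax(ax)
    ax.plot(result.period_h, result.Q, label=str(result.label))
    if not np.all(np.isnan(result.threshold)):
        ax.plot(result.period_h, result.threshold, "--", color="grey",
                label="significance")
    ax.set_xlabel("period (h)")
    ax.set_ylabel(r"$\chi^2$ statistic Q")
    ax.legend()
    return ax


def plot_state_occupancy(occupancy: pd.DataFrame, ax=None):
    """Fraction of time in each sleep stage by ZT."""
    ax = _ensure_ax(ax)
    for state, sub in occupancy.groupby("state"):
        sub = sub.sort_values("zt_bin")
        ax.plot(sub["zt_bin"], sub["fraction"], label=str(state))
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel("fraction of bins")
    ax.legend()
    return ax


def plot_decision_surface(surface: dict, ax=None):
    """SVM decision regions over the first two principal axes."""
    ax = _ensure_ax(ax)
    labels = surface["grid_labels"]
    classes = np.unique(labels)
    codes = np.searchsorted(classes, labels)
    ax.contourf(surface["xx"], surface["yy"], codes,
                levels=np.arange(len(classes) + 1) - 0.5,
                cmap="Pastel1", alpha=0.8)
    pts = surface["points"]
    for lab, sub in pts.groupby("label"):
        ax.scatter(sub["pc1"], sub["pc2"], label=str(lab), s=18,
                   edgecolor="k", linewidth=0.3)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.legend()
    return ax
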