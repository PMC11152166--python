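"""Figure helpers: probability trajectories, embeddings, thermal summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .events import ProbabilityTrajectory
from .taxonomy import EventLabel


def plot_trajectory(traj: ProbabilityTrajectory, ax=None):
    """Per-event probability time series for one embryo."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for ev in EventLabel:
        ax.plot(traj.hours, traj.column(ev), label=ev.display_name)
    ax.set(xlabel="hour", ylabel="event probability", ylim=(0, 1), title=traj.embryo_id)
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_projection(proj: pd.DataFrame, color_by: str = "event", ax=None):
    """2D embedding scatter coloured by event class or relative time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if color_by == "relative_time":
        sc = ax.scatter(proj["x"], proj["y"], c=proj["relative_time"], s=8, cmap="viridis")
        plt.colorbar(sc, ax=ax, label="relative developmental time")
    else:
        for name, sub in proj.groupby("event"):
            ax.scatter(sub["x"], sub["y"], s=8, label=name)
        ax.legend(fontsize=7)
    ax.set(xlabel="dim 1", ylabel="dim 2")
    return ax


def plot_treatment_summary(summary: pd.DataFrame, ax=None):
    """Mean +/- 1 s.d. onset hour per event across temperatures."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name, sub in summary.groupby("event"):
        sub = sub.sort_values("treatment")
        ax.errorbar(
            sub["treatment"], sub["mean_onset_hour"], yerr=sub["sd_onset_hour"],
            marker="o", capsize=2, label=name,
        )
    ax.set(xlabel="temperature (°C)", ylabel="onset hour (mean ± s.d.)")
    ax.legend(fontsize=7)
    return ax
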