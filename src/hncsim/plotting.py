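"""Minimal plotting helpers: clone heatmaps and trajectory lines."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .io import CloneMatrix, sort_clones_by_peak
from .simulate import Trajectory

__all__ = ["plot_clone_heatmap", "plot_trajectory"]


def plot_clone_heatmap(matrix: CloneMatrix, ax: Optional[plt.Axes] = None,
                       sort: bool = True, log: bool = True) -> plt.Axes:
    """Heatmap of clone sizes over time, rows sorted by peak timepoint."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = sort_clones_by_peak(matrix) if sort else matrix.clones
    idx = [matrix.clones.index(c) for c in order]
    data = matrix.counts[idx].astype(float)
    if log:
        data = np.log1p(data)
    ax.imshow(data, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel(f"time ({matrix.time_unit})")
    ax.set_ylabel("clone (sorted by peak)" if sort else "clone")
    return ax


def plot_trajectory(traj: Trajectory, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Clone-size time series, one line per clone, on calibrated time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for k in range(traj.states.shape[1]):
        ax.plot(traj.times, traj.states[:, k], lw=0.8)
    ax.set_xlabel("calibrated time")
    ax.set_ylabel("clone size")
    return ax
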