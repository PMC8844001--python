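"""Small plotting helpers for fitted states and occupancy trajectories."""
from __future__ import annotations

import numpy as np

from .mtd import devectorize_upper

__all__ = ["plot_centroid_matrix", "plot_occupancy_trajectories"]


def plot_centroid_matrix(centroid_vector: np.ndarray, n_roi: int | None = None, ax=None):
    """Heatmap of one state's centroid coupling pattern."""
    import matplotlib.pyplot as plt

    vec = np.asarray(centroid_vector, dtype=float)
    if n_roi is None:
        n_roi = int(round((1 + np.sqrt(1 + 8 * len(vec))) / 2))
    mat = devectorize_upper(vec, n_roi)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    lim = np.abs(mat).max() or 1.0
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xlabel("ROI")
    ax.set_ylabel("ROI")
    ax.figure.colorbar(im, ax=ax, shrink=0.8, label="coupling")
    return ax


def plot_occupancy_trajectories(occ, states: dict[str, int], ax=None):
    """Per-subject occupancy trajectories over RS1-RS3 with grand means,
    one panel per named state."""
    import matplotlib.pyplot as plt

    runs = ["RS1", "RS2", "RS3"]
    if ax is None:
        _, axes = plt.subplots(1, len(states), figsize=(3.2 * len(states), 3), sharey=True)
    else:
        axes = np.atleast_1d(ax)
    for axis, (label, state) in zip(np.ravel(axes), states.items()):
        sub = occ[occ["state"] == state].pivot_table(
            index="subject", columns="run", values="proportion"
        ).reindex(columns=runs)
        for _, row in sub.iterrows():
            axis.plot(runs, row.to_numpy(), color="grey", alpha=0.3, lw=0.8)
        axis.plot(runs, sub.mean().to_numpy(), color="crimson", lw=2.5, marker="o")
        axis.set_title(label)
        axis.set_ylabel("fractional occupancy")
    return axes
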