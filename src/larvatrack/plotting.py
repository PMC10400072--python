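"""Matplotlib helpers for the standard report panels."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_navigation_index", "plot_variability_decomposition",
           "plot_speed_and_turn_rate", "plot_trajectory"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_navigation_index(series_df, ax=None):
    """Windowed navigation index over time (one line per animal)."""
    ax = _ax(ax)
    for key, g in series_df.groupby("id") if "id" in series_df else [(0, series_df)]:
        mid = (g["start_frame"] + g["end_frame"]) / 2.0
        ax.plot(mid, g["index"], label=f"animal {key}")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("frame")
    ax.set_ylabel("navigation index ⟨vx⟩/⟨v⟩")
    return ax


def plot_variability_decomposition(dec, ax=None):
    """Per-animal densities (thin), their mean, and the population-mean
    density, in the style of an intra/inter-animal comparison panel."""
    ax = _ax(ax)
    for row in dec.per_animal:
        ax.plot(dec.grid, row, color="thistle", lw=0.7, alpha=0.7)
    ax.plot(dec.grid, dec.mean_of_intra, color="purple", lw=2.0,
            label="mean of individual densities")
    ax.plot(dec.grid, dec.population, color="crimson", lw=2.0,
            label="population-mean density")
    ax.set_xlabel("navigation index")
    ax.set_ylabel("probability density")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_speed_and_turn_rate(t_s, speed, turn_rate, ax=None):
    """Population speed and turn rate on twin axes."""
    ax = _ax(ax)
    ax.plot(t_s, speed, color="tab:blue", label="speed")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("speed (mm/s)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(t_s, turn_rate, color="tab:orange", label="turn rate")
    ax2.set_ylabel("turn rate (/min)", color="tab:orange")
    return ax


def plot_trajectory(x_mm, y_mm, states=None, ax=None):
    """Path in mm, optionally coloured by run (red) / turn (blue) state."""
    ax = _ax(ax)
    x = np.asarray(x_mm)
    y = np.asarray(y_mm)
    if states is None:
        ax.plot(x, y, color="0.3", lw=0.8)
    else:
        s = np.asarray(states)
        turn = (s == "turn") | (s == 1)
        ax.plot(x, y, color="tab:red", lw=0.8)
        ax.scatter(x[turn], y[turn], s=2.0, color="tab:blue")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax
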