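"""Static map and time-series plots of pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_occurrence_map", "plot_annual_area"]


def plot_occurrence_map(grid: np.ndarray, title: str = "Accumulated predicted fire occurrence", path=None):
    """Render an occurrence-count (or binary prediction) grid as a map."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.asarray(grid), cmap="YlOrRd", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="fire occurrences")
    ax.set_title(title)
    ax.set_xlabel("column (km)")
    ax.set_ylabel("row (km)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_annual_area(summaries, path=None):
    """Bar chart of predicted fire area by year, relative to the period mean."""
    years = [s.year for s in summaries]
    pct = [s.pct_of_period_mean for s in summaries]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(years, pct, color="firebrick")
    ax.axhline(100.0, color="k", lw=0.8, ls="--")
    ax.set_ylabel("% of period mean area")
    ax.set_xlabel("year")
    ax.set_title("Predicted fire area by year")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
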