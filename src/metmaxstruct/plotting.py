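"""Figure export: heatmaps, cumulative rank curves, fraction-vs-α plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .compare import SimilarityMatrix, SweepResult, cumulative_curve

# dark blue (0) to buff orange (1): a perceptually ordered two-color ramp
_CMAP = matplotlib.colors.LinearSegmentedColormap.from_list(
    "similarity", ["#08306b", "#f5c877"]
)


def plot_heatmap(matrix: SimilarityMatrix, path: str | Path) -> None:
    """One similarity heatmap; the filename should embed the (α, β) label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap=_CMAP, vmin=0, vmax=1, aspect="auto")
    ax.set_xlabel(f"targets (n={len(matrix.target_ids)})")
    ax.set_ylabel(f"queries (n={len(matrix.query_ids)})")
    ax.set_title(f"Tversky α={matrix.params.alpha:g}, β={matrix.params.beta:g}")
    fig.colorbar(im, ax=ax, label="similarity")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cumulative_curves(sweep: SweepResult, path: str | Path) -> None:
    """All grid points' max-similarity curves, descending vs rank fraction."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for params, prof in zip(sweep.grid, sweep.profiles):
        curve = cumulative_curve(prof)
        ax.plot(
            curve["rank_fraction"],
            curve["similarity"],
            label=f"α={params.alpha:g}",
            lw=1.2,
        )
    ax.set_xlabel("rank fraction")
    ax.set_ylabel("max similarity to any target")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=2)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fraction_vs_alpha(
    summary: pd.DataFrame, threshold: float, path: str | Path
) -> None:
    """Secondary plot: fraction of queries above a threshold as a function of α."""
    col = f"frac_gt_{threshold:g}"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(summary["alpha"], summary[col], "o-")
    ax.set_xlabel("Tversky α")
    ax.set_ylabel(f"fraction of queries with max similarity > {threshold:g}")
    ax.set_ylim(-0.02, 1.02)
    fig.savefig(path, dpi=120)
    plt.close(fig)
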