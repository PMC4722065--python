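"""Figure helpers for sweep results.

Raw-grid summaries only: heatmaps of mean directional error over the
FOV x resolution grid per displacement distance, error-versus-distance
curves per world type, and error versus subfield count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiment import aggregate

_TYPE_COLOURS = {
    "trees_only": "tab:green",
    "trees_and_tussocks": "tab:blue",
    "tussocks_only": "tab:red",
}


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_error_vs_distance(records: pd.DataFrame, path=None):
    """Mean directional error (95% CI) against displacement per world type."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    for wt, grp in records.groupby("world_type"):
        agg = aggregate(grp, "displacement_m").sort_values("displacement_m")
        colour = _TYPE_COLOURS.get(wt)
        ax.errorbar(
            agg.displacement_m,
            agg["mean"],
            yerr=1.96 * agg["sem"].fillna(0.0),
            label=wt,
            color=colour,
            marker="o",
            capsize=2,
        )
    ax.axhline(90.0, ls="--", c="k", lw=1, label="chance (90 deg)")
    ax.set_xscale("log")
    ax.set_xlabel("displacement from route (m)")
    ax.set_ylabel("directional error (deg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_fov_px_heatmaps(records: pd.DataFrame, path=None):
    """One heatmap of mean error per displacement distance, FOV x pixels."""
    plt = _mpl()
    distances = sorted(records.displacement_m.unique())
    fovs = sorted(records.fov.unique())
    pxs = sorted(records.px.unique())
    fig, axes = plt.subplots(
        1, len(distances), figsize=(3 * len(distances), 3), squeeze=False
    )
    for ax, dist in zip(axes[0], distances):
        sub = records[records.displacement_m == dist]
        agg = aggregate(sub, ["fov", "px"])
        grid = np.full((len(pxs), len(fovs)), np.nan)
        for row in agg.itertuples(index=False):
            grid[pxs.index(row.px), fovs.index(row.fov)] = row.mean
        im = ax.imshow(
            grid, origin="lower", cmap="gray_r", vmin=0, vmax=120, aspect="auto"
        )
        ax.set_xticks(range(len(fovs)), fovs, fontsize=6, rotation=90)
        ax.set_yticks(range(len(pxs)), pxs, fontsize=6)
        ax.set_xlabel("FOV (deg)", fontsize=7)
        ax.set_ylabel("azimuthal pixels", fontsize=7)
        ax.set_title(f"{dist} m", fontsize=8)
        fig.colorbar(im, ax=ax, label="mean error (deg)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sector_curves(records: pd.DataFrame, path=None):
    """Mean error against displacement for each subfield count."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    for n, grp in records.groupby("n_sectors"):
        agg = aggregate(grp, "displacement_m").sort_values("displacement_m")
        ax.errorbar(
            agg.displacement_m,
            agg["mean"],
            yerr=1.96 * agg["sem"].fillna(0.0),
            label=f"{n} subfield{'s' if n > 1 else ''}",
            marker="o",
            capsize=2,
        )
    ax.set_xlabel("displacement from route (m)")
    ax.set_ylabel("directional error (deg)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
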