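"""Figure-style panels for spore morphometry.

Three panels mirroring the usual presentation of spore-size and concavity
data: a length-width scatter with per-species isoprobability ellipses, a
2-D kernel-density panel, and a violin plot of the suprahilar-depression
percentage with significance stars from pairwise tests.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .stats import compare_groups, iso_ellipse, kde2

__all__ = ["size_scatter_with_ellipses", "size_kde_panel", "depression_violin"]


def _ellipse_patch(ep, **kw):
    return mpatches.Ellipse(
        ep.center, 2 * ep.semi_major, 2 * ep.semi_minor, angle=ep.angle_deg,
        fill=False, **kw,
    )


def size_scatter_with_ellipses(df, prob_level=0.95, ax=None,
                               length_col="L_um", width_col="W_um",
                               species_col="species"):
    """Length-width scatter with one isoprobability ellipse per species."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    palette = sns.color_palette("deep", df[species_col].nunique())
    for (label, g), color in zip(df.groupby(species_col, sort=False), palette):
        ax.scatter(g[length_col], g[width_col], s=14, color=color, label=label)
        if len(g) >= 3:
            ep = iso_ellipse(g[[length_col, width_col]].to_numpy(), prob_level)
            ax.add_patch(_ellipse_patch(ep, edgecolor=color, lw=1.5))
    ax.set_xlabel("spore length (µm)")
    ax.set_ylabel("spore width (µm)")
    ax.legend(fontsize=7)
    return ax


def size_kde_panel(df, ax=None, length_col="L_um", width_col="W_um",
                   species_col="species"):
    """Kernel-density contours of the length-width cloud per species."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    palette = sns.color_palette("deep", df[species_col].nunique())
    for (label, g), color in zip(df.groupby(species_col, sort=False), palette):
        if len(g) < 3:
            continue
        grid = kde2(g[[length_col, width_col]].to_numpy())
        ax.contour(grid.x, grid.y, grid.density, levels=4, colors=[color])
        ax.scatter(g[length_col], g[width_col], s=10, color=color, label=label)
    ax.set_xlabel("spore length (µm)")
    ax.set_ylabel("spore width (µm)")
    ax.legend(fontsize=7)
    return ax


def depression_violin(df, ax=None, value_col="depression_pct",
                      species_col="species", method="mw"):
    """Violin of the depression percentage with pairwise significance stars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    order = list(df[species_col].unique())
    sns.violinplot(data=df, x=species_col, y=value_col, order=order,
                   inner="point", cut=0, ax=ax)
    ymax = df[value_col].max()
    step = 0.1 * max(ymax, 1.0)
    h = ymax + step
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a = df.loc[df[species_col] == order[i], value_col]
            b = df.loc[df[species_col] == order[j], value_col]
            if min(len(a), len(b)) < 2:
                continue
            res = compare_groups(a, b, method=method)
            ax.plot([i, j], [h, h], color="k", lw=0.8)
            ax.text((i + j) / 2, h + 0.1 * step, res.stars, ha="center", fontsize=8)
            h += step
    ax.set_ylabel("suprahilar depression (% of hull area)")
    ax.tick_params(axis="x", labelsize=7)
    return ax
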