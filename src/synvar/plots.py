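"""Summary figures: order distribution, CV bars, similarity levels, rVAF grid."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_order_distribution", "plot_cv", "plot_similarity_levels", "plot_rvaf_grid"]


def plot_order_distribution(orders: dict, ax=None):
    """Bar chart of how many extractions selected each synergy count."""
    if ax is None:
        _, ax = plt.subplots()
    vals = np.asarray(sorted(orders.values()))
    uniq, counts = np.unique(vals, return_counts=True)
    ax.bar(uniq, counts, color="0.4")
    for u, c in zip(uniq, counts):
        ax.text(u, c, f"{100 * c / vals.size:.0f}%", ha="center", va="bottom")
    ax.set_xlabel("number of synergies")
    ax.set_ylabel("extractions")
    return ax


def plot_cv(per_subject: dict, all_level: float, ax=None, ylabel="CV"):
    """Per-subject CV bars with the pooled 'All' level as a dashed line."""
    if ax is None:
        _, ax = plt.subplots()
    subjects = sorted(per_subject)
    ax.bar([f"S{s + 1}" for s in subjects], [per_subject[s] for s in subjects], color="0.6")
    ax.axhline(all_level, linestyle="--", color="k", label="All")
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax


def plot_similarity_levels(intra_values, inter_values, random_values, ax=None):
    """Box plot of the per-subject similarity at the three levels."""
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot([intra_values, inter_values, random_values],
               tick_labels=["intra", "inter", "random"])
    ax.set_ylabel("synergy similarity")
    return ax


def plot_rvaf_grid(table, ax=None):
    """Heatmap of the source-subject x target-repetition rVAF grid."""
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(table.values, aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("target (subject, repetition)")
    ax.set_ylabel("source subject")
    plt.colorbar(im, ax=ax, label="rVAF")
    return ax
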