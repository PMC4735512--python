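"""Summary figures for CLI runs: concentration sweeps and ratio tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_sweep_summary", "plot_ratio_track", "plot_cluster_sizes"]


def plot_sweep_summary(summary, path) -> None:
    """Cluster count, median diameter and contact frequency vs concentration,
    one line per model variant."""
    metrics = ["cluster_count_mean", "median_diameter", "contact_frequency"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    for ax, metric in zip(axes, metrics):
        for variant, group in summary.groupby("variant"):
            ax.plot(group["n_exog"], group[metric], marker="o", label=variant)
        ax.set_xlabel("exogenous binders")
        ax.set_ylabel(metric.replace("_", " "))
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ratio_track(bedgraph, path, title: str = "") -> None:
    """Test/control ratio - 1 along the genome (gains up, losses down)."""
    mid = 0.5 * (bedgraph["start"] + bedgraph["end"])
    fig, ax = plt.subplots(figsize=(10, 2.6))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.fill_between(mid, 0, bedgraph["ratio"],
                    where=bedgraph["ratio"] >= 0, color="tab:blue", step="mid")
    ax.fill_between(mid, 0, bedgraph["ratio"],
                    where=bedgraph["ratio"] < 0, color="tab:red", step="mid")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("ratio - 1")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_sizes(diameters, weights, path, bins=30) -> None:
    """Localization-weighted histogram of cluster diameters (log x)."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    lo = max(float(np.min(diameters)), 1.0)
    edges = np.logspace(np.log10(lo), np.log10(float(np.max(diameters)) + 1), bins)
    ax.hist(diameters, bins=edges, weights=weights / np.sum(weights))
    ax.set_xscale("log")
    ax.set_xlabel("cluster diameter (nm)")
    ax.set_ylabel("fraction of localizations")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
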