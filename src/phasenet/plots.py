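"""Convenience plots for the analysis results (matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd

PHASE_COLORS = {
    "chronic": "#e6c300",
    "accelerated": "#d62728",
    "blast": "#6baed6",
    "resistant": "#2ca02c",
}


def plot_pca(pca_result, meta: pd.DataFrame, ax=None):
    """Scatter of samples on the first two principal components, phase-colored."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    phase = meta.set_index("sample_id")["phase"]
    scores = pca_result.scores
    for name, color in PHASE_COLORS.items():
        ids = [s for s in scores.index if phase.get(s) == name]
        if ids:
            ax.scatter(scores.loc[ids, "PC1"], scores.loc[ids, "PC2"],
                       s=18, c=color, label=name)
    vf = pca_result.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}% variance)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_volcano(de_table: pd.DataFrame, q_cut: float = 0.05, ax=None):
    """log2 fold change vs -log10 p, calls colored."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    logp = -np.log10(np.maximum(de_table["p"].to_numpy(), 1e-300))
    colors = de_table["call"].map(
        {"under": "#3182bd", "over": "#de2d26", "unchanged": "0.7"}
    )
    ax.scatter(de_table["log2fc"], logp, s=6, c=colors)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    return ax


def plot_degree_distribution(network, ax=None):
    """Out- and in-degree histograms of a network or consensus network."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    out_deg = network.out_degrees()
    in_deg = network.in_degrees()
    top = int(max(out_deg.max(), in_deg.max(), 1))
    bins = np.arange(top + 2) - 0.5
    ax.hist(out_deg, bins=bins, alpha=0.6, label="out-degree", color="#de2d26")
    ax.hist(in_deg, bins=bins, alpha=0.6, label="in-degree", color="#3182bd")
    ax.set_xlabel("degree")
    ax.set_ylabel("genes")
    ax.legend(frameon=False, fontsize=8)
    return ax
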