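"""Figure export, separated from computation so tests run headless."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .annotate import EnrichmentMatrix
from .profiles import BinQuant, ProfileMatrix


def plot_aggregate_curves(curves: pd.DataFrame, path, title: str = "") -> None:
    """Mean profile per factor around the anchor (offset 0)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for factor, sub in curves.groupby("factor"):
        ax.plot(sub["offset"], sub["mean"], label=str(factor))
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("mean log2 ChIP/input")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile_heatmap(matrix: ProfileMatrix, path, title: str = "") -> None:
    """Anchor-by-position heat map, rows ordered by descending mean."""
    vals = matrix.values
    order = np.argsort(-np.nansum(np.nan_to_num(vals), axis=1))
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(
        vals[order],
        aspect="auto",
        interpolation="nearest",
        extent=[-matrix.flank, matrix.flank, len(vals), 0],
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="log2 signal")
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("anchors")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_heatmap(matrix: EnrichmentMatrix, path) -> None:
    """Factor x class heat map: -log10 p as color, overlap counts as labels."""
    neg = matrix.neg_log10_p()
    counts = matrix.counts()
    fig, ax = plt.subplots(figsize=(1.2 * len(neg.columns) + 2, 0.6 * len(neg) + 2))
    im = ax.imshow(neg.to_numpy(), aspect="auto", cmap="Reds")
    ax.set_xticks(range(len(neg.columns)), neg.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(neg.index)), neg.index)
    for i in range(len(neg.index)):
        for j in range(len(neg.columns)):
            ax.text(j, i, int(counts.iat[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="-log10 p (hypergeometric)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bin_quant(quant: BinQuant, path, title: str = "") -> None:
    """Violin + notched box of per-bin log2 signal per group."""
    groups = list(quant.summaries)
    data = [
        quant.bins.loc[quant.bins["group"] == g, "value"].dropna().to_numpy()
        for g in groups
    ]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.violinplot(data, showextrema=False)
    ax.boxplot(data, notch=True, showfliers=False, widths=0.2)
    ax.set_xticks(range(1, len(groups) + 1), groups, rotation=45, ha="right")
    ax.set_ylabel("log2 signal per bin")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
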