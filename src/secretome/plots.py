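"""Figure helpers for the main pipeline outputs.

Kept deliberately thin: each function draws one standard view (kinetic
scatter, enrichment dot plot, PCA biplot, consensus heatmap, volcano table)
and returns the matplotlib figure; callers decide where to save.  Proteins
with non-positive abundance delta P are kept in tables but excluded from
log10-flux displays, where the logarithm is undefined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "plot_k_vs_flux",
    "plot_enrichment_dots",
    "plot_pca",
    "plot_consensus",
    "plot_volcano",
]


def plot_k_vs_flux(kinetics: pd.DataFrame, cutoff: float = 0.01):
    """Rate constant k against log10 flux, cutoff marked; positive flux only."""
    fig, ax = plt.subplots(figsize=(5, 4))
    shown = kinetics.loc[kinetics["flux"] > 0]
    colors = shown["classification"].map(
        {"secreted": "tab:red", "intracellular": "tab:blue"}
    ).fillna("grey")
    ax.scatter(np.log10(shown["flux"]), shown["k"], s=12, c=colors, alpha=0.7)
    ax.axhline(cutoff, color="red", lw=1, ls="--", label=f"k = {cutoff:g}")
    ax.set_yscale("log")
    ax.set_xlabel("log10 flux (intensity / h)")
    ax.set_ylabel("k (1/h)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_enrichment_dots(enrichment: pd.DataFrame, top: int = 15):
    """Dot plot of top enriched terms: gene ratio vs term, size = overlap."""
    shown = enrichment.nsmallest(top, "p_value").iloc[::-1]
    ratio = shown["k_selected"] / shown["n_selected"]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(shown) + 1.5))
    sc = ax.scatter(
        ratio,
        np.arange(len(shown)),
        s=20 * shown["k_selected"].clip(lower=1),
        c=shown["q_value"],
        cmap="viridis_r",
    )
    ax.set_yticks(np.arange(len(shown)))
    ax.set_yticklabels(
        [n if n else t for t, n in zip(shown["term"], shown["term_name"])]
    )
    ax.set_xlabel("gene ratio")
    fig.colorbar(sc, ax=ax, label="adjusted p")
    fig.tight_layout()
    return fig


def plot_pca(scores: pd.DataFrame, variance, metadata: pd.DataFrame):
    """PC1/PC2 sample map coloured by tissue, marker by sex."""
    meta = metadata.set_index("sample_id").loc[scores.index]
    fig, ax = plt.subplots(figsize=(5, 4))
    for tissue, color in (("ASC", "tab:orange"), ("BMSC", "tab:purple")):
        for sex, marker in (("F", "o"), ("M", "^")):
            mask = (meta["tissue"] == tissue) & (meta["sex"] == sex)
            ax.scatter(
                scores.loc[mask, "PC1"],
                scores.loc[mask, "PC2"],
                c=color,
                marker=marker,
                label=f"{tissue}/{sex}",
            )
    ax.set_xlabel(f"PC1 ({100 * variance[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * variance[1]:.0f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_consensus(model):
    """Consensus co-clustering heatmap for one NMF rank."""
    order = np.argsort(model.assignments.to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(model.consensus[np.ix_(order, order)], cmap="RdBu_r", vmin=0, vmax=1)
    ax.set_title(f"rank {model.rank} (cophenetic {model.cophenetic:.3f})")
    fig.colorbar(im, ax=ax, label="co-clustering frequency")
    fig.tight_layout()
    return fig


def plot_volcano(
    results: pd.DataFrame,
    fc_col: str = "log2fc_tissue",
    q_col: str = "q_tissue_BMSC",
    fc_threshold: float = 0.6,
):
    """log2 fold change against -log2 q for the tissue contrast."""
    fig, ax = plt.subplots(figsize=(5, 4))
    neglog_q = -np.log2(results[q_col].clip(lower=1e-300))
    hits = (results[q_col] < 0.05) & (results[fc_col].abs() > fc_threshold)
    ax.scatter(results[fc_col], neglog_q, s=14, c=np.where(hits, "tab:red", "grey"))
    ax.axvline(fc_threshold, color="k", lw=0.5, ls=":")
    ax.axvline(-fc_threshold, color="k", lw=0.5, ls=":")
    ax.axhline(-np.log2(0.05), color="k", lw=0.5, ls=":")
    ax.set_xlabel("log2 fold change (BMSC / ASC)")
    ax.set_ylabel("-log2 q")
    fig.tight_layout()
    return fig
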