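"""Figure helpers: zonation line plots with SEM bands, embeddings, bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_zonation_profiles", "plot_embedding", "plot_composition"]


def plot_zonation_profiles(
    profiles_by_condition: dict,
    genes: list[str],
    path: str | Path,
    ncols: int = 4,
) -> None:
    """Per-gene segment line plots, one panel per gene, SEM as a hue band."""
    n = len(genes)
    ncols = min(ncols, max(1, n))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.4 * nrows), squeeze=False)
    for k, gene in enumerate(genes):
        axk = axes[k // ncols][k % ncols]
        for cond, prof in profiles_by_condition.items():
            s = prof.summary[prof.summary["gene"] == gene].sort_values("segment")
            x = s["segment"].to_numpy()
            m = s["mean_density"].to_numpy()
            e = s["sem"].to_numpy()
            axk.plot(x, m, marker="o", ms=3, label=cond)
            axk.fill_between(x, m - e, m + e, alpha=0.25)
        axk.set_title(gene, fontsize=9)
        axk.set_xticks(range(1, int(s["segment"].max()) + 1))
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    axes[0][0].legend(fontsize=7)
    fig.supxlabel("segment (CV → PV)")
    fig.supylabel("density (counts / px²)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(model, color: str, path: str | Path) -> None:
    """Scatter the 2D embedding coloured by an obs column (e.g. cluster, zone)."""
    emb = model.embedding
    vals = model.adata.obs[color].astype(str)
    fig, ax = plt.subplots(figsize=(5, 4))
    for v in sorted(vals.unique()):
        m = (vals == v).to_numpy()
        ax.scatter(emb[m, 0], emb[m, 1], s=4, label=v, alpha=0.7)
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    ax.legend(markerscale=2, fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_composition(composition: pd.DataFrame, path: str | Path) -> None:
    """Stacked per-condition cluster-fraction bars."""
    frac_cols = [c for c in composition.columns if c.startswith("frac_")]
    conds = [c[5:] for c in frac_cols]
    fig, ax = plt.subplots(figsize=(4, 4))
    bottoms = np.zeros(len(conds))
    for _, row in composition.iterrows():
        vals = np.array([row[f"frac_{c}"] for c in conds])
        ax.bar(conds, vals, bottom=bottoms, label=f"C{row['cluster']}")
        bottoms += vals
    ax.set_ylabel("fraction of cells")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
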