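"""Hepatocyte clustering on the zonated marker panel.

Normalised hepatocyte expression of a 16-gene zonated marker panel
(8 pericentral, 1 midzonal, 7 periportal genes) is z-scored, reduced by
PCA, embedded with UMAP and partitioned by Leiden community detection on a
k-nearest-neighbour graph. Clusters are annotated with the zone whose
marker set they express most strongly, cluster composition is compared
across conditions (Fisher exact enrichment per cluster), and spatial
segment labels can be projected back onto the embedding to connect the
expression-space clusters with their histological location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel",
    "ClusterModel",
    "normalize_counts",
    "cluster_cells",
    "co_cluster",
    "annotate_clusters",
    "compare_composition",
    "backmap_segments",
]

DEFAULT_RESOLUTION = 0.8  # tuned on synthetic control lobules to give 5-6 clusters


@dataclass(frozen=True)
class MarkerPanel:
    """The 16-gene zonated marker panel used for hepatocyte clustering."""

    pericentral: tuple[str, ...] = (
        "Cldn2", "Lect2", "Glul", "Oat", "Cyp1a2", "Cyp2e1", "Gstm1", "Rgn",
    )
    midzonal: tuple[str, ...] = ("Pon1",)
    periportal: tuple[str, ...] = (
        "Gls2", "G6pc", "Fbp1", "Hsd17b13", "Vtn", "Cyp2f2", "Pigr",
    )

    def __post_init__(self) -> None:
        sets = [set(self.pericentral), set(self.midzonal), set(self.periportal)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("marker sets must be disjoint")

    @property
    def all(self) -> list[str]:
        return list(self.pericentral) + list(self.midzonal) + list(self.periportal)

    @property
    def zones(self) -> dict[str, tuple[str, ...]]:
        return {
            "pericentral": self.pericentral,
            "midzonal": self.midzonal,
            "periportal": self.periportal,
        }


@dataclass
class ClusterModel:
    """Result of panel-restricted clustering.

    ``adata`` is the panel-subset AnnData carrying cluster labels
    (``obs["cluster"]``), the UMAP embedding (``obsm["X_umap"]``), PCA
    loadings (``varm["PCs"]``) and, for co-clustered data, the condition
    label per cell.
    """

    adata: ad.AnnData
    seed: int
    resolution: float

    @property
    def labels(self) -> pd.Series:
        return self.adata.obs["cluster"]

    @property
    def embedding(self) -> np.ndarray:
        return self.adata.obsm["X_umap"]


def normalize_counts(counts: ad.AnnData) -> ad.AnnData:
    """Median-total scaling followed by log1p.

    Every cell is scaled so its total equals the median per-cell total,
    making the normalised vector invariant to uniform count doubling; the
    pre-log scaled values are kept in ``layers["norm"]`` (used for fold
    changes) and ``X`` holds ``log1p`` of them.
    """
    totals = np.asarray(counts.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-total cell reached normalisation; QC must exclude it")
    adata = counts.copy()
    sc.pp.normalize_total(adata, target_sum=None)
    adata.layers["norm"] = adata.X.copy()
    sc.pp.log1p(adata)
    return adata


def _check_panel(adata: ad.AnnData, panel: MarkerPanel) -> None:
    missing = [g for g in panel.all if g not in adata.var_names]
    if missing:
        raise ValueError(f"marker panel gene(s) missing from the matrix: {missing}")


def _embed_and_cluster(sub: ad.AnnData, seed: int, resolution: float) -> ad.AnnData:
    n_comps = min(10, sub.n_vars - 1, sub.n_obs - 1)
    sc.tl.pca(sub, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(sub, n_neighbors=15, random_state=seed)
    sc.tl.leiden(
        sub, resolution=resolution, random_state=seed, key_added="cluster",
        flavor="igraph", n_iterations=2, directed=False,
    )
    sc.tl.umap(sub, random_state=seed)
    return sub


def cluster_cells(
    normalized: ad.AnnData,
    panel: MarkerPanel | None = None,
    seed: int = 0,
    resolution: float = DEFAULT_RESOLUTION,
) -> ClusterModel:
    """Cluster hepatocytes on the marker panel.

    Restricts to the panel genes, z-scores each gene, reduces to at most
    10 principal components, builds a 15-NN graph and partitions it with
    Leiden at ``resolution``; a 2D UMAP is attached for display. Fully
    deterministic under ``seed``.
    """
    panel = panel or MarkerPanel()
    _check_panel(normalized, panel)
    if normalized.n_obs < 20:
        raise ValueError("need at least 20 cells to cluster")
    sub = normalized[:, panel.all].copy()
    sc.pp.scale(sub)
    sub = _embed_and_cluster(sub, seed, resolution)
    return ClusterModel(sub, seed, resolution)


def co_cluster(
    normalized_by_condition: dict[str, ad.AnnData],
    panel: MarkerPanel | None = None,
    seed: int = 0,
    resolution: float = DEFAULT_RESOLUTION,
    scale: str = "joint",
) -> ClusterModel:
    """Joint clustering of two or more conditions.

    Integration is deliberately light: the per-cell normalised matrices
    are concatenated and z-scored *jointly* (``scale="joint"``) before the
    shared PCA / graph / Leiden run. Joint scaling preserves genuine
    between-condition expression shifts — a gene uniformly suppressed in
    one condition stays low there — whereas anchor-based integration, or
    z-scoring within each condition (available as
    ``scale="per-condition"``), would standardise the very shift whose
    effect on cluster composition is being measured. The condition label
    is kept per cell in ``obs["condition"]``.
    """
    panel = panel or MarkerPanel()
    if scale not in ("joint", "per-condition"):
        raise ValueError("scale must be 'joint' or 'per-condition'")
    subs = []
    for cond, adata in normalized_by_condition.items():
        if adata.n_obs == 0:
            raise ValueError(f"condition {cond!r} has no cells")
        _check_panel(adata, panel)
        sub = adata[:, panel.all].copy()
        if scale == "per-condition":
            sc.pp.scale(sub)
        sub.obs["condition"] = cond
        sub.obs_names = [f"{cond}:{n}" for n in sub.obs_names]
        subs.append(sub)
    joint = ad.concat(subs, join="inner", merge="same")
    if scale == "joint":
        sc.pp.scale(joint)
    joint = _embed_and_cluster(joint, seed, resolution)
    return ClusterModel(joint, seed, resolution)


def annotate_clusters(
    model: ClusterModel,
    normalized: ad.AnnData | None = None,
    panel: MarkerPanel | None = None,
) -> dict[str, str]:
    """Assign each cluster the zone whose markers it expresses most.

    Per cluster, the mean z-score of each zone's marker set is computed on
    the (already z-scored) panel matrix; the cluster is labelled with the
    argmax zone, or "unresolved" on an exact tie. The annotation is also
    written to ``model.adata.obs["zone"]``.
    """
    panel = panel or MarkerPanel()
    adata = model.adata
    zmat = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    labels = model.labels
    annotation: dict[str, str] = {}
    for cl in labels.cat.categories if hasattr(labels, "cat") else sorted(labels.unique()):
        cells = labels == cl
        scores = {
            zone: float(zmat.loc[cells, list(genes)].to_numpy().mean())
            for zone, genes in panel.zones.items()
        }
        best = max(scores.values())
        top = [z for z, v in scores.items() if v == best]
        annotation[str(cl)] = top[0] if len(top) == 1 else "unresolved"
    adata.obs["zone"] = labels.astype(str).map(annotation)
    return annotation


def compare_composition(
    model: ClusterModel,
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Cluster composition and per-cluster enrichment across two conditions.

    For each cluster a 2x2 table (condition x in/out of cluster) yields an
    odds ratio and two-sided Fisher exact p-value, Benjamini-Hochberg
    adjusted across clusters; per-condition cell fractions sum to 1.
    """
    obs = model.adata.obs
    if condition_key not in obs:
        raise ValueError(f"no {condition_key!r} column; cluster conditions jointly first")
    conds = list(pd.unique(obs[condition_key]))
    if len(conds) != 2:
        raise ValueError(f"composition comparison needs exactly 2 conditions, got {conds}")
    a, b = conds
    labels = obs["cluster"].astype(str)
    n_a = int((obs[condition_key] == a).sum())
    n_b = int((obs[condition_key] == b).sum())
    recs = []
    for cl in sorted(labels.unique(), key=lambda s: (len(s), s)):
        in_a = int(((labels == cl) & (obs[condition_key] == a)).sum())
        in_b = int(((labels == cl) & (obs[condition_key] == b)).sum())
        table = [[in_b, n_b - in_b], [in_a, n_a - in_a]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        recs.append(
            {
                "cluster": cl,
                f"n_{a}": in_a,
                f"n_{b}": in_b,
                f"frac_{a}": in_a / n_a,
                f"frac_{b}": in_b / n_b,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(recs)
    out["p_adj"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    if "zone" in obs:
        zone_map = obs.groupby(labels, observed=True)["zone"].agg(
            lambda s: s.mode().iat[0]
        )
        out["zone"] = out["cluster"].map(zone_map)
    return out


def backmap_segments(
    model: ClusterModel,
    segment_assignment: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach spatial segment labels to the embedding.

    ``segment_assignment`` must carry cell_id and segment columns (from
    :func:`lobulemap.zonation.assign_to_segments` on cell centroids).
    Cells without a segment (outside every grid) are excluded, with the
    count logged. Returns the per-cell overlay (cluster, zone, segment,
    embedding coordinates) and the cluster x segment contingency table.
    """
    adata = model.adata
    overlay = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "cluster": model.labels.astype(str).to_numpy(),
            "x_emb": model.embedding[:, 0],
            "y_emb": model.embedding[:, 1],
        }
    )
    if "zone" in adata.obs:
        overlay["zone"] = adata.obs["zone"].to_numpy()
    seg = segment_assignment.dropna(subset=["segment"]).copy()
    seg["segment"] = seg["segment"].astype(int)
    # co-clustered obs names are "<condition>:<cell_id>"
    key = overlay["cell_id"].str.split(":").str[-1]
    overlay["segment"] = key.map(seg.set_index("cell_id")["segment"])
    n_missing = int(overlay["segment"].isna().sum())
    if n_missing:
        logger.info("%d cells lack a segment assignment; excluded from overlay", n_missing)
    overlay = overlay.dropna(subset=["segment"])
    overlay["segment"] = overlay["segment"].astype(int)
    contingency = pd.crosstab(overlay["cluster"], overlay["segment"])
    return overlay, contingency
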