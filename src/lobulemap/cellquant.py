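"""Spot-to-cell assignment, count matrices and cell-level QC.

Front end of the single-cell pipeline: decoded transcript spots are
assigned to segmented cell outlines by 2D point-in-polygon containment,
aggregated into a cell x gene count matrix (an :class:`anndata.AnnData`),
and filtered by total-count QC and by "any expression" of a set of
non-hepatocyte marker genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "assign_spots_to_cells",
    "qc_filter_cells",
    "filter_non_hepatocytes",
]

DEFAULT_NON_HEP_MARKERS = ("Lrat", "Pecam1", "Ptprc", "Lyz2", "Adgre1")


@dataclass
class QCParams:
    """Cell-level quality-control settings.

    ``min_total`` removes cells with fewer than that many transcripts in
    total (default 10, i.e. cells with less than a 10-gene-count are
    dropped). ``non_hep_markers`` define non-hepatocytes by *any*
    expression (count >= 1); they are removed when ``remove_non_hep`` is
    set — typically for hepatocyte-focused comparisons such as control
    versus Wnt-agonist treatment.
    """

    min_total: int = 10
    non_hep_markers: tuple[str, ...] = DEFAULT_NON_HEP_MARKERS
    remove_non_hep: bool = True

    def __post_init__(self) -> None:
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")


def assign_spots_to_cells(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    genes: list[str] | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Assign each spot to the cell polygon containing its (x, y).

    Containment includes the boundary; a spot claimed by several
    (overlapping) polygons goes to the smallest by area, with a logged
    warning. Spots inside no polygon are returned as the unassigned table,
    so assigned + unassigned always equals the input count.

    Parameters
    ----------
    spots : DataFrame with columns x, y, gene (z ignored: containment is 2D).
    cells : DataFrame with columns cell_id and polygon (shapely Polygons),
        as produced by the simulator or read from GeoJSON outlines.
    genes : column universe of the count matrix; defaults to the genes
        observed in ``spots``.

    Returns
    -------
    (counts, unassigned) : AnnData of integer counts (obs = cells in input
    order, var = genes) with per-cell totals in ``obs["total_counts"]``
    and cell centroid/type columns when available, plus the unassigned
    spot rows.
    """
    if genes is None:
        genes = sorted(spots["gene"].unique())
    gene_idx = {g: j for j, g in enumerate(genes)}
    unknown = set(spots["gene"]) - set(gene_idx)
    if unknown:
        raise ValueError(f"spots contain genes outside the panel: {sorted(unknown)[:5]}")

    polys = list(cells["polygon"])
    tree = STRtree(polys)
    pts = shapely.points(spots["x"].to_numpy(float), spots["y"].to_numpy(float))
    cand_pt, cand_poly = tree.query(pts, predicate="intersects")  # boundary counts

    assigned = np.full(len(spots), -1, dtype=np.int64)
    areas = cells["area"].to_numpy(float) if "area" in cells else np.array(
        [p.area for p in polys]
    )
    n_overlap = 0
    order = np.argsort(areas[cand_poly], kind="stable")
    for k in order:
        i = cand_pt[k]
        if assigned[i] == -1:
            assigned[i] = cand_poly[k]
        else:
            n_overlap += 1
    if n_overlap:
        logger.warning(
            "%d spots claimed by overlapping polygons; assigned to the smaller cell",
            n_overlap,
        )

    inside = assigned >= 0
    rows = assigned[inside]
    cols = spots["gene"].map(gene_idx).to_numpy()[inside]
    mat = sparse.coo_matrix(
        (np.ones(inside.sum(), dtype=np.int64), (rows, cols)),
        shape=(len(cells), len(genes)),
    ).tocsr()

    obs = pd.DataFrame(index=pd.Index(cells["cell_id"].astype(str), name="cell_id"))
    for col in ("x", "y", "area", "cell_type", "t"):
        if col in cells:
            obs[col] = cells[col].to_numpy()
    counts = ad.AnnData(X=mat, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    counts.obs["total_counts"] = np.asarray(mat.sum(axis=1)).ravel()
    unassigned = spots.loc[~inside].copy()
    return counts, unassigned


def qc_filter_cells(counts: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Drop cells whose total transcript count is below ``min_total``.

    A cell with total exactly ``min_total`` is retained. Idempotent; the
    decision is recorded in ``obs["passed_qc"]`` of the returned copy.
    """
    params = params or QCParams()
    totals = np.asarray(counts.X.sum(axis=1)).ravel()
    counts = counts.copy()
    counts.obs["total_counts"] = totals
    counts.obs["passed_qc"] = totals >= params.min_total
    out = counts[counts.obs["passed_qc"]].copy()
    return out


def filter_non_hepatocytes(counts: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Flag (and optionally remove) cells expressing non-hepatocyte markers.

    A cell is non-hepatocyte if it has *any* expression — a count of one
    or more — of any marker in ``params.non_hep_markers``. The flag is
    stored in ``obs["is_hepatocyte"]``; flagged cells are removed when
    ``params.remove_non_hep`` is set.

    Raises
    ------
    ValueError
        Naming any marker gene absent from the matrix.
    """
    params = params or QCParams()
    missing = [g for g in params.non_hep_markers if g not in counts.var_names]
    if missing:
        raise ValueError(f"non-hepatocyte marker gene(s) not in panel: {missing}")
    sub = counts[:, list(params.non_hep_markers)].X
    marker_any = np.asarray((sub > 0).sum(axis=1)).ravel() > 0
    counts = counts.copy()
    counts.obs["is_hepatocyte"] = ~marker_any
    if params.remove_non_hep:
        return counts[counts.obs["is_hepatocyte"]].copy()
    return counts
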