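"""File formats: spot tables, cell outlines, count matrices, codebooks, configs.

Everything the pipeline persists is plain text: TSV spot tables, GeoJSON
cell outlines (QuPath-style exports are accepted), MatrixMarket count
matrices with genes/cells sidecar files, JSON codebooks and QC reports,
and YAML configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse
from shapely.geometry import Polygon, mapping, shape

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_spot_table",
    "write_spot_table",
    "read_cell_outlines",
    "write_cell_outlines",
    "read_counts_mtx",
    "write_counts_mtx",
    "write_counts_tsv",
    "write_image_stacks",
    "read_image_stacks",
    "read_axis_annotations",
    "write_axis_annotations",
    "load_config",
    "save_config",
    "sha256sum",
]


class FormatError(ValueError):
    """A file does not match the expected format."""


SPOT_COLUMNS = ("x", "y", "gene")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV spot table (requires x, y, gene; z and score optional).

    Unknown columns are preserved. Rows with non-numeric coordinates are
    rejected; their line numbers are logged.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    n0 = len(df)
    for col in ("x", "y") + (("z",) if "z" in df else ()):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["x", "y"]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path.name, int(bad.sum()), lines[:20])
        df = df[~bad].reset_index(drop=True)
    if "spot_id" not in df:
        df.insert(0, "spot_id", [f"spot_{i:06d}" for i in range(len(df))])
    logger.info("read %d/%d spots from %s", len(df), n0, path)
    return df


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    cols = ["spot_id", "x", "y", "z", "gene", "score"]
    out = spots[[c for c in cols if c in spots.columns]
                + [c for c in spots.columns if c not in cols and c != "polygon"]]
    out.to_csv(path, sep="\t", index=False)


def read_cell_outlines(path: str | Path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection of cell polygons.

    ``cell_id`` is taken from the feature properties (``cell_id``,
    ``name`` or ``id``, in that order — covering QuPath-style exports) or
    auto-assigned; duplicates are deduplicated with a suffix. Non-polygon
    geometries raise a :class:`FormatError`.
    """
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    seen: dict[str, int] = {}
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(
                f"{path}: feature {i} has non-polygon geometry {geom.get('type')!r}"
            )
        poly = shape(geom)
        props = feat.get("properties") or {}
        cid = props.get("cell_id") or props.get("name") or props.get("id")
        if cid is None:
            cid = f"cell_{i:04d}"
            logger.info("feature %d has no cell id; assigned %s", i, cid)
        cid = str(cid)
        if cid in seen:
            seen[cid] += 1
            new = f"{cid}_{seen[cid]}"
            logger.warning("duplicate cell_id %r renamed to %r", cid, new)
            cid = new
        else:
            seen[cid] = 0
        c = poly.centroid
        rows.append(
            {"cell_id": cid, "x": c.x, "y": c.y, "area": poly.area,
             "cell_type": props.get("cell_type", "unknown"), "polygon": poly}
        )
    return pd.DataFrame(rows)


def write_cell_outlines(cells: pd.DataFrame, path: str | Path) -> None:
    feats = []
    for _, row in cells.iterrows():
        props = {"cell_id": str(row["cell_id"])}
        if "cell_type" in row:
            props["cell_type"] = str(row["cell_type"])
        if "t" in row and pd.notna(row["t"]):
            props["t"] = float(row["t"])
        feats.append(
            {"type": "Feature", "geometry": mapping(row["polygon"]), "properties": props}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_counts_mtx(counts: ad.AnnData, outdir: str | Path) -> None:
    """Write matrix.mtx + genes.tsv + cells.tsv (with obs columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = counts.X if sparse.issparse(counts.X) else sparse.csr_matrix(np.asarray(counts.X))
    scipy_io.mmwrite(outdir / "matrix.mtx", X.astype(np.int64))
    pd.Series(counts.var_names, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    obs = counts.obs.reset_index()
    obs.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_counts_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (indir / name).exists():
            raise FormatError(f"{indir}: missing {name}")
    X = sparse.csr_matrix(scipy_io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].astype(str)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t")
    obs = obs.set_index(obs.columns[0])
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def write_counts_tsv(counts: ad.AnnData, path: str | Path) -> None:
    """Single wide TSV alternative: cells x genes."""
    X = counts.X.toarray() if sparse.issparse(counts.X) else np.asarray(counts.X)
    pd.DataFrame(X, index=counts.obs_names, columns=counts.var_names).to_csv(
        path, sep="\t"
    )


def read_axis_annotations(path: str | Path) -> list:
    """CSV with columns region_id, cv_x, cv_y, pv_x, pv_y."""
    from .zonation import AxisAnnotation

    df = pd.read_csv(path)
    required = ["region_id", "cv_x", "cv_y", "pv_x", "pv_y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        AxisAnnotation(
            str(r.region_id), (float(r.cv_x), float(r.cv_y)),
            (float(r.pv_x), float(r.pv_y)), source="manual",
        )
        for r in df.itertuples()
    ]


def write_axis_annotations(annotations: list, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"region_id": a.region_id, "cv_x": a.cv[0], "cv_y": a.cv[1],
             "pv_x": a.pv[0], "pv_y": a.pv[1], "source": a.source}
            for a in annotations
        ]
    ).to_csv(path, index=False)


def write_image_stacks(stacks: dict, outdir: str | Path) -> list[Path]:
    """Write (round, channel) stacks as multi-page TIFFs (r{i}_c{j}.tif, 1-based)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (r, c), stack in stacks.items():
        p = outdir / f"r{r + 1}_c{c + 1}.tif"
        tifffile.imwrite(p, np.asarray(stack, dtype=np.float32))
        paths.append(p)
    return paths


def read_image_stacks(indir: str | Path, rounds: int, channels: int) -> dict:
    import tifffile

    indir = Path(indir)
    stacks = {}
    for r in range(rounds):
        for c in range(channels):
            p = indir / f"r{r + 1}_c{c + 1}.tif"
            if not p.exists():
                raise FormatError(f"missing image stack {p}")
            stacks[(r, c)] = tifffile.imread(p)
    return stacks


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def sha256sum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
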