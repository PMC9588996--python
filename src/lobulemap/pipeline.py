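"""End-to-end orchestration: simulate → (decode) → quantify → zonate → cluster → compare.

A run is driven by a plain YAML/dict configuration with explicit seeds.
Every stage writes its outputs (and the resolved configuration) under the
output directory; any stage can instead start from files on disk. The run
report records per-stage record counts, wall-clock times, warnings and a
checksum manifest of every file written, so a run is reproducible from its
resolved config and seeds alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .cellquant import QCParams, assign_spots_to_cells, filter_non_hepatocytes, qc_filter_cells
from .clustering import (
    DEFAULT_RESOLUTION,
    MarkerPanel,
    annotate_clusters,
    backmap_segments,
    cluster_cells,
    co_cluster,
    compare_composition,
    normalize_counts,
)
from .codebook import ImagingConfig, build_codebook
from .decoder import DecoderParams, decode_experiment
from .figures import plot_composition, plot_embedding, plot_zonation_profiles
from .synthetic import (
    LobuleGeometry,
    RenderParams,
    default_panel,
    default_scenario,
    render_image_rounds,
    simulate_lobule,
    simulate_spot_field,
    simulate_spots,
)
from .zonation import (
    AxisAnnotation,
    assign_to_segments,
    build_segment_grid,
    classify_zonation_pattern,
    combine_profiles,
    detect_landmarks,
    differential_zonation,
    quantify_segment_profiles,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "RunReport", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "conditions": ["control", "dko"],
    "simulate": {
        "enabled": True,
        "n_cells": 800,
        "n_genes": 100,
        "n_regions": 3,
        "background_fraction": 0.02,
    },
    "decode": {
        "enabled": False,
        "n_spots": 300,
        "n_genes": 24,
        "n_unused": 8,
    },
    "quantify": {"min_total": 10, "remove_non_hep": True},
    "zonate": {"n_segments": 9, "lateral_extension": 500.0, "auto_landmarks": True,
               "axes_csv": None},
    "cluster": {"resolution": DEFAULT_RESOLUTION},
    "inputs": {},
}


@dataclass
class RunReport:
    """What a pipeline run did: stage records, warnings, output manifest."""

    stages: list[dict] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def add_stage(self, name: str, t0: float, **counts) -> None:
        self.stages.append({"stage": name, "wall_s": round(time.time() - t0, 2), **counts})

    def add_file(self, path: Path) -> None:
        self.manifest[str(path)] = lio.sha256sum(path)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"stages": self.stages, "wall_clock_s": round(self.wall_clock_s, 2),
                 "manifest": self.manifest},
                indent=1,
            )
        )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | None = None, outdir: str | Path = "lobulemap_run") -> RunReport:
    """Execute the configured stages for every condition.

    Simulation produces ``n_regions`` replicate lobule fields per
    condition (replicate CV→PV regions, as replicate regions are drawn on
    a real slide); quantification, zonation profiling and clustering
    follow; with exactly two conditions a joint clustering, composition
    comparison, per-gene differential test and pattern classification are
    added. Missing stage inputs raise errors naming the producing stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    t_start = time.time()
    seed = int(cfg["seed"])
    panel = default_panel(int(cfg["simulate"]["n_genes"]))
    lio.save_config(cfg, outdir / "config.resolved.yaml")
    report.add_file(outdir / "config.resolved.yaml")

    spots_by: dict[str, pd.DataFrame] = {}
    cells_by: dict[str, pd.DataFrame] = {}
    geometry = LobuleGeometry()

    # --- simulate (or load) -------------------------------------------------
    for ci, cond in enumerate(cfg["conditions"]):
        cdir = outdir / cond
        cdir.mkdir(exist_ok=True)
        t0 = time.time()
        if cfg["simulate"]["enabled"]:
            scen = default_scenario(cond, panel)
            frames, cell_frames = [], []
            for r in range(int(cfg["simulate"]["n_regions"])):
                rseed = seed + 1000 * (ci + 1) + r
                _, cells = simulate_lobule(
                    rseed, geometry, n_cells=int(cfg["simulate"]["n_cells"])
                )
                sp, _ = simulate_spots(
                    cells, panel, scen, seed=rseed + 500, geometry=geometry,
                    background_fraction=float(cfg["simulate"]["background_fraction"]),
                )
                sp["region"] = f"{cond}_r{r}"
                cells = cells.copy()
                cells["region"] = f"{cond}_r{r}"
                cells["cell_id"] = [f"{cond}_r{r}_{c}" for c in cells["cell_id"]]
                frames.append(sp)
                cell_frames.append(cells)
            spots = pd.concat(frames, ignore_index=True)
            spots["spot_id"] = [f"spot_{i:07d}" for i in range(len(spots))]
            cells = pd.concat(cell_frames, ignore_index=True)
            lio.write_spot_table(spots, cdir / "spots.tsv")
            lio.write_cell_outlines(cells, cdir / "cells.geojson")
            report.add_file(cdir / "spots.tsv")
            report.add_file(cdir / "cells.geojson")
        else:
            inputs = cfg["inputs"].get(cond) or {}
            if "spots" not in inputs or "cells" not in inputs:
                raise ValueError(
                    f"simulate disabled and no spots/cells inputs for condition "
                    f"{cond!r}: provide them or enable the simulate stage"
                )
            spots = lio.read_spot_table(inputs["spots"])
            cells = lio.read_cell_outlines(inputs["cells"])
            if "region" not in spots:
                spots["region"] = f"{cond}_r0"
            if "region" not in cells:
                cells["region"] = f"{cond}_r0"
        spots_by[cond] = spots
        cells_by[cond] = cells
        report.add_stage(f"simulate[{cond}]", t0, n_spots=len(spots), n_cells=len(cells))

    # --- optional imaging + decode demo ------------------------------------
    if cfg["decode"]["enabled"]:
        t0 = time.time()
        cb = build_codebook(
            int(cfg["decode"]["n_genes"]),
            gene_names=panel.names[: int(cfg["decode"]["n_genes"])],
            n_unused=int(cfg["decode"]["n_unused"]),
            seed=seed,
        )
        cb.write_json(outdir / "codebook.json")
        field_spots = simulate_spot_field(
            int(cfg["decode"]["n_spots"]), cb.genes, seed=seed + 7
        )
        stacks, transforms, _ = render_image_rounds(field_spots, cb, seed=seed + 8)
        result = decode_experiment(stacks, cb)
        lio.write_spot_table(result.spots, outdir / "decoded_spots.tsv")
        qc = result.qc
        (outdir / "decode_qc.json").write_text(
            json.dumps(
                {
                    "n_used_matches": qc.n_used_matches,
                    "n_unused_matches": qc.n_unused_matches,
                    "specificity_estimate": qc.specificity_estimate,
                    "transforms": [
                        {"round": r + 1, "angle_rad": tr.angle, "dx": tr.translation[0],
                         "dy": tr.translation[1]}
                        for r, tr in enumerate(result.transforms)
                    ],
                },
                indent=1,
            )
        )
        report.add_file(outdir / "decoded_spots.tsv")
        report.add_file(outdir / "decode_qc.json")
        report.add_stage("decode", t0, n_transcripts=len(result.spots))

    # --- quantify ------------------------------------------------------------
    qc_params = QCParams(
        min_total=int(cfg["quantify"]["min_total"]),
        remove_non_hep=bool(cfg["quantify"]["remove_non_hep"]),
    )
    hep_by: dict[str, object] = {}
    norm_by: dict[str, object] = {}
    for cond in cfg["conditions"]:
        t0 = time.time()
        # replicate regions share the pixel frame, so assignment runs per
        # region and the matrices are stacked afterwards
        import anndata as _ad

        parts, n_unassigned = [], 0
        for region in pd.unique(spots_by[cond]["region"]):
            sp = spots_by[cond][spots_by[cond]["region"] == region]
            ce = cells_by[cond][cells_by[cond]["region"] == region].reset_index(drop=True)
            part, una = assign_spots_to_cells(sp, ce, genes=panel.names)
            parts.append(part)
            n_unassigned += len(una)
        counts = _ad.concat(parts, join="outer", merge="same") if len(parts) > 1 else parts[0]
        unassigned = pd.DataFrame(index=range(n_unassigned))
        kept = qc_filter_cells(counts, qc_params)
        hep = filter_non_hepatocytes(kept, qc_params)
        cdir = outdir / cond
        lio.write_counts_mtx(hep, cdir / "counts")
        for f in ("matrix.mtx", "genes.tsv", "cells.tsv"):
            report.add_file(cdir / "counts" / f)
        hep_by[cond] = hep
        norm_by[cond] = normalize_counts(hep)
        report.add_stage(
            f"quantify[{cond}]", t0, n_cells_in=counts.n_obs, n_cells_qc=kept.n_obs,
            n_hepatocytes=hep.n_obs, n_unassigned=len(unassigned),
        )

    # --- zonate ---------------------------------------------------------------
    zc = cfg["zonate"]
    profiles_by = {}
    seg_assign_by = {}
    for cond in cfg["conditions"]:
        t0 = time.time()
        spots = spots_by[cond]
        grids = []
        region_profiles = []
        for region, sub in spots.groupby("region"):
            if zc.get("axes_csv"):
                annos = lio.read_axis_annotations(zc["axes_csv"])
            elif zc["auto_landmarks"]:
                annos = detect_landmarks(sub)
            else:
                raise ValueError("zonate stage needs axes_csv or auto_landmarks")
            if not annos:
                logger.warning("no axis found for region %s", region)
                continue
            region_grids = [
                build_segment_grid(
                    AxisAnnotation(f"{region}_{a.region_id}", a.cv, a.pv, a.source),
                    float(zc["lateral_extension"]), int(zc["n_segments"]),
                )
                for a in annos
            ]
            grids.append((region, region_grids))
            region_profiles.append(
                quantify_segment_profiles(sub, region_grids, genes=panel.names)
            )
        if not region_profiles:
            raise ValueError(f"no CV-PV axes for condition {cond!r} (zonate stage)")
        prof = combine_profiles(region_profiles)
        cdir = outdir / cond
        prof.per_region.to_csv(cdir / "profiles_per_region.tsv", sep="\t", index=False)
        prof.summary.to_csv(cdir / "profiles_summary.tsv", sep="\t", index=False)
        report.add_file(cdir / "profiles_per_region.tsv")
        report.add_file(cdir / "profiles_summary.tsv")
        profiles_by[cond] = prof
        # segment assignment of QC-passed cells, per region
        hep = hep_by[cond]
        cell_pos = hep.obs.reset_index()[["cell_id", "x", "y"]]
        assigns = []
        for region, region_grids in grids:
            pos = cell_pos[cell_pos["cell_id"].str.startswith(f"{region}_")]
            for grid in region_grids:
                a = assign_to_segments(pos, grid)
                assigns.append(a.dropna(subset=["segment"]))
        seg_assign_by[cond] = (
            pd.concat(assigns).drop_duplicates("cell_id")
            if assigns
            else pd.DataFrame(columns=["cell_id", "segment"])
        )
        report.add_stage(f"zonate[{cond}]", t0, n_regions=sum(len(g) for _, g in grids))

    marker_genes = [g for g in MarkerPanel().all if g in panel.names]
    fig_genes = marker_genes[:8]
    plot_zonation_profiles(profiles_by, fig_genes, outdir / "zonation_profiles.png")
    report.add_file(outdir / "zonation_profiles.png")

    # --- cluster (+ compare when two conditions) ------------------------------
    t0 = time.time()
    resolution = float(cfg["cluster"]["resolution"])
    if len(cfg["conditions"]) == 2:
        model = co_cluster(norm_by, seed=seed, resolution=resolution)
    else:
        only = cfg["conditions"][0]
        model = cluster_cells(norm_by[only], seed=seed, resolution=resolution)
        model.adata.obs["condition"] = only
    annotation = annotate_clusters(model)
    seg_all = pd.concat(seg_assign_by.values(), ignore_index=True)
    overlay, contingency = backmap_segments(model, seg_all)
    cluster_table = pd.DataFrame(
        {
            "cell_id": model.adata.obs_names,
            "condition": model.adata.obs["condition"].to_numpy(),
            "cluster": model.labels.astype(str).to_numpy(),
            "zone": model.adata.obs["zone"].to_numpy(),
            "x_emb": model.embedding[:, 0],
            "y_emb": model.embedding[:, 1],
        }
    )
    cluster_table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    overlay.to_csv(outdir / "cluster_segment_overlay.tsv", sep="\t", index=False)
    contingency.to_csv(outdir / "cluster_segment_contingency.tsv", sep="\t")
    plot_embedding(model, "cluster", outdir / "umap_clusters.png")
    plot_embedding(model, "zone", outdir / "umap_zones.png")
    for f in ("clusters.tsv", "cluster_segment_overlay.tsv",
              "cluster_segment_contingency.tsv", "umap_clusters.png", "umap_zones.png"):
        report.add_file(outdir / f)
    report.add_stage("cluster", t0, n_clusters=len(annotation))

    if len(cfg["conditions"]) == 2:
        t0 = time.time()
        cond_a, cond_b = cfg["conditions"]
        comp = compare_composition(model)
        comp.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        plot_composition(comp, outdir / "composition.png")

        def norm_frame(cond):
            hep = norm_by[cond]
            layer = hep.layers["norm"]
            arr = layer.toarray() if hasattr(layer, "toarray") else np.asarray(layer)
            return pd.DataFrame(arr, index=hep.obs_names, columns=hep.var_names)

        diff = differential_zonation(norm_frame(cond_a), norm_frame(cond_b))
        patterns = classify_zonation_pattern(profiles_by[cond_a], profiles_by[cond_b])
        diff = diff.merge(patterns, on="gene", how="left")
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        for f in ("composition.tsv", "composition.png", "differential.tsv"):
            report.add_file(outdir / f)
        report.add_stage("compare", t0, n_genes=len(diff))

    report.wall_clock_s = time.time() - t_start
    report.write(outdir / "run_report.json")
    return report
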