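# lobulemap

Combinatorial-FISH spot decoding and liver-lobule zonation analysis, driven
by a fully synthetic lobule simulator.

Hepatocyte gene expression is zonated along the lobule axis that runs from
the central vein (CV, "pericentral", zone 3) to the portal vein (PV,
"periportal", zone 1). Multiplexed single-molecule FISH platforms read out
~100 transcripts at single-cell resolution by imaging each tissue region
over several rounds and colour channels: every gene is assigned a binary
on/off code across the round × channel grid, and a transcript reveals its
identity through the pattern of images in which its fluorescent spot
appears. `lobulemap` re-implements the two analysis pipelines such
experiments need, together with a ground-truth generator so every stage is
testable without any microscope data:

* **Spot decoding** — background correction, per-plane maxima detection
  calibrated to a target of `slice area (µm²) × 0.5` maxima, z-grouping of
  maxima across adjacent slices, iterative-closest-point (ICP) rigid
  alignment of every imaging round onto round 1, trilinear rigid
  resampling, per-pixel 16-value profile matching against the codebook
  (used + unused decoy codes, cosine score), connected-component transcript
  calling, and specificity estimation from the used/unused call ratio.
* **Per-cell quantification (pipeline 1)** — point-in-polygon assignment of
  decoded spots to segmented cell outlines, total-count QC (cells with
  fewer than 10 transcripts are dropped), removal of non-hepatocytes (any
  expression of Lrat, Pecam1, Ptprc, Lyz2 or Adgre1), median-total
  normalisation, and PCA → k-NN → Leiden clustering of hepatocytes on a
  16-gene zonated marker panel (8 pericentral, 1 midzonal, 7 periportal)
  with UMAP display, zone annotation, and cross-condition composition
  statistics (Fisher exact, Benjamini–Hochberg).
* **Axis profiling (pipeline 2)** — CV→PV axes (auto-detected from
  landmark genes Cyp2e1/Glul/Sox9, or supplied manually), a band of
  ±500 px around each axis divided into 9 equal segments, per-gene
  transcript density (counts/px²) per segment averaged across replicate
  regions (mean ± SEM), per-gene differential expression (fold change +
  two-sided Wilcoxon rank-sum on per-cell normalised expression), and
  classification of zonation-change patterns (pericentral loss; ectopic
  pericentral gain with periportal decrease / no change / increase).
* **Synthetic lobule generator** — Voronoi-tessellated cells (85%
  hepatocytes), per-cell Poisson counts following pericentral
  (exponential), midzonal (Gaussian bump), periportal (logistic) or flat
  profiles of the lobule coordinate `t = d_CV / (d_CV + d_PV)`, 2%
  uniform background spots, and optional rendering of 8-round × 2-channel
  encoded image stacks with per-round rigid drift. Scenarios model loss of
  endothelial Wnt ligands (`dko`: pericentral suppression +
  "periportalization") and systemic Wnt agonism (`agonist`: pericentral
  expansion without periportal loss).

## Worked example

Simulate a control and a knockout slide (two replicate regions each), run
both pipelines, and compare:

```python
from lobulemap.pipeline import run_pipeline

report = run_pipeline(
    {"seed": 0, "simulate": {"n_regions": 2, "n_cells": 600}},
    "run",
)
for stage in report.stages:
    print(stage)
```

```
{'stage': 'simulate[control]', 'wall_s': 1.5, 'n_spots': 124445, 'n_cells': 1200}
{'stage': 'simulate[dko]', 'wall_s': 1.52, 'n_spots': 128897, 'n_cells': 1200}
{'stage': 'quantify[control]', 'wall_s': 0.56, 'n_cells_in': 1200, 'n_cells_qc': 1142, 'n_hepatocytes': 934, 'n_unassigned': 15}
{'stage': 'quantify[dko]', 'wall_s': 0.37, 'n_cells_in': 1200, 'n_cells_qc': 1152, 'n_hepatocytes': 923, 'n_unassigned': 14}
{'stage': 'zonate[control]', 'wall_s': 0.12, 'n_regions': 2}
{'stage': 'zonate[dko]', 'wall_s': 0.13, 'n_regions': 2}
{'stage': 'cluster', 'wall_s': 14.51, 'n_clusters': 7}
{'stage': 'compare', 'wall_s': 0.21, 'n_genes': 100}
```

`run/differential.tsv` then contains, per gene, the knockout-vs-control
fold change, rank-sum p-value and per-band pattern class:

```
  gene  fold_change        p_adj pc_change pp_change                  pattern_class
  Glul     0.157923 1.204379e-89      down      down                        PC loss
Cyp2e1     0.149892 1.175529e-89      down      down                        PC loss
  Gls2     1.674934 2.950079e-55        up unchanged ectopic PC gain + PP unchanged
  Ass1     2.288998 1.179261e-91        up        up        ectopic PC gain + PP up
 Fads1     1.284934 4.882055e-17        up      down      ectopic PC gain + PP down
 Ccnd1     1.009161 1.000000e+00 unchanged unchanged                      no change
```

The suppressed Wnt targets (Glul, Cyp2e1) come back at the injected 0.15×
suppression as fold changes ≈ 0.15 and are classified as pericentral loss,
while the periportal genes gain an ectopic pericentral component whose
periportal baseline falls (Fads1), stays (Gls2) or rises (Ass1) — the
three "periportalization" patterns. `run/composition.tsv` shows the
cluster shift (summed periportal-annotated cluster fractions 0.36 in
control → 0.60 in the knockout), and `run/cluster_segment_overlay.tsv`
traces each spatial segment back onto the UMAP.

The same stages are available from the shell:

```sh
lobulemap simulate --scenario control --seed 1 --out sim/
lobulemap quantify --spots sim/spots.tsv --cells sim/cells.geojson --out counts/
lobulemap zonate   --spots sim/spots.tsv --out zonation/
lobulemap decode   --images imgs/ --codebook cb.json --out spots.tsv
lobulemap run      --seed 0 --out run/
```

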