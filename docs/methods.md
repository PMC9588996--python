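# Methods

This note documents the models, algorithms and numerical choices behind
`lobulemap`, and what the synthetic benchmark does and does not establish
about real data.

## The synthetic lobule

**Geometry and coordinates.** A field of 3000 × 1800 px (pixel size
0.138 µm) holds one central vein (CV) at (500, 900) and one portal vein
(PV) at (2500, 900), each a 60 px-radius lumen devoid of cells and
transcripts. Coordinates are 0-based pixels, origin top-left, x rightward,
y downward; z is the imaging slice index. Multiple CV–PV pairs are
supported; each CV pairs with its nearest PV.

**Lobule coordinate.** Every cell carries a ground-truth position
`t = d_CV / (d_CV + d_PV)` on its nearest axis pair — exactly 0 at the CV
centre and 1 at the PV centre, concentric around each vein. A clamped
projection onto the axis line was considered and rejected: it assigns
t = 0 to *all* tissue beyond the CV, producing a large flat plateau of
maximal pericentral expression that no real lobule shows and that makes
density-based vein detection ill-posed. The distance-ratio form is the
standard lobule coordinate in the zonation literature and reproduces the
halo-like expression around veins.

**Cells.** A jittered hexagonal lattice (pitch from the target cell count,
jitter ±0.25 pitch) is tessellated by Voronoi regions, mirrored across the
field edges so all regions are finite, clipped to the field and cut by the
vein lumens: non-overlapping polygons tiling the parenchyma. 85% of cells
are hepatocytes; of the rest, 10% are cholangiocytes seated in the cells
closest to a PV (bile ducts hug the portal tract — this also gives the
Sox9 landmark its anatomical meaning), and the remainder are endothelial
(45%), immune (35%) and stellate (20%) cells placed at random.

**Expression model.** Each panel gene has a cell class (it is expressed
only in cells of that type) and a zonation class with a parametric profile
of `t`, scaled by `base_rate` (expected transcripts per cell at the
profile peak):

| class | profile | defaults |
|---|---|---|
| pericentral | `exp(-t/τ)` | τ = 0.30 |
| periportal | logistic `1/(1+exp(-(t-m)/s))` | m = 0.60, s = 0.12 |
| midzonal | `exp(-(t-c)²/2w²)` | c = 0.45, w = 0.13 |
| nonzonated | constant | — |

Per cell × gene counts are Poisson with these means; spot positions are
uniform inside the cell polygon. Base rates: 8/cell for the 16 zonated
marker genes, 5/cell for the additional named zonated genes, 3/cell for
nonzonated hepatocyte genes, 6–8/cell for non-hepatocyte markers, 1.5/cell
for the synthetic filler genes that pad the panel to 100. This yields
~130 transcripts per hepatocyte, a realistic order for 100-plex FISH.
2% of all emitted spots are uniform background with random gene labels
(false positives are known to exist on these platforms; no rate is
published, so the fraction is configurable).

**Scenarios.** `dko` (loss of endothelial Wnt ligands) multiplies every
pericentral hepatocyte gene by 0.15 everywhere and adds to every
periportal hepatocyte gene an ectopic pericentral component — a
truncated-shifted exponential `(exp(-t/τ) − exp(-t₀/τ))/(1 − exp(-t₀/τ))`
with t₀ = 0.9, scaled to the gene's base rate — while the native
periportal profile is multiplied by 0.5 / 1 / 1.5 according to the gene's
mode (the three observed "periportalization" patterns). The truncation
makes a mode-1 gene *exactly* equal to control in deep periportal
territory, which is the defining property of that pattern. `agonist`
replaces each pericentral Wnt-target profile with its peak value at all
t (expansion across the lobule) and leaves periportal genes untouched.

**Imaging.** Each spot is rendered as an isotropic Gaussian blob
(σ_xy = 1 px, σ_z = 0.8 slices, amplitude 100 ± 20%) into the (round,
channel) stacks where its binary code is "on" — 16 stacks of 8 z-slices
for the default 8-round × 2-channel protocol. Rounds 2+ receive a random
rigid drift (rotation ≤3° about the field centre, shift ≤5 px per axis);
round 1 is the reference. Spots drifting out of the field are clipped and
counted.

**What the generator does not model:** optical blur differences between
channels, chromatic aberration, illumination fields, autofluorescence
texture, z-drift, cell-boundary segmentation errors, doublets, and
biological covariance between genes beyond the shared `t`. Passing tests
therefore demonstrate algorithmic correctness under the stated noise
model, not end-to-end performance on microscope data.

## Codebooks

Constant-weight binary codes (default weight 4 of 16 bits, pairwise
Hamming distance ≥ 4) are selected greedily from a seeded shuffle of all
`C(16,4) = 1820` candidates. A reserve of unused codes (default 8) is
carried through decoding as decoys: the fraction of calls landing on a
used code estimates specificity. Bit order is round-major,
channel-minor and fixed in the JSON format. The real platform's code
parameters are proprietary; everything is configurable.

## Decoding

1. **Background**: per-plane Gaussian high-pass (σ = 10 px ≈ 10× the PSF),
   negatives clipped.
2. **Maxima**: strict 8-neighbour maxima per plane, annotated with
   absolute brightness, local background (mean of a 2–5 px annulus) and
   periphery (mean of the 8 neighbours). Thresholds on
   (B_abs − B_back) and (B_peri − B_back) (the latter at 0.25× the former)
   are bisected (≤30 iterations) until the retained count is within 10%
   of `n_planes × slice area (µm²) × 0.5`. The initial candidate set is
   everything; fields sparser than the target keep all candidates.
3. **Z-groups**: maxima within 2 px in adjacent slices are chained
   (union-find); chains of ≥2 count as one candidate signal whose
   brightest member represents it in the round's feature cloud.
4. **Registration**: each round's cloud is aligned to round 1 by trimmed
   ICP with a closed-form 2D rigid fit (Kabsch). Three robustness layers
   were required because a weight-4 code puts each spot in at most 4 of 8
   rounds, so two round clouds share only ~30–45% of their points:
   * *multi-start* — identity, the modal displacement vector between the
     clouds (2D histogram of nearest-displacements), and a ±1–3° rotation
     sweep about the cloud centroid each followed by its modal
     displacement; the candidate with the most 1.5 px-inliers wins;
   * *distance-gated refinement with IRLS* — once coarsely aligned, a
     shrinking correspondence gate replaces the fixed-fraction trim
     (which systematically drags the fit when many points are unpaired),
     and final Tukey-biweight reweighting removes the residual bias from
     spurious matches inside the gate;
   * *consensus pass* — rounds whose fit has < 40% inliers are re-fit
     against the union of all confidently registered clouds, which covers
     essentially every spot and so removes the partial-overlap problem.
   On noise-free fixtures this registers every round to ≤ 0.4 px mean
   error; rounds with < 3 features fall back to identity with a warning.
5. **Resampling**: stacks are resampled by the inverse transform with a
   trilinear kernel (z unchanged by the in-plane transform, so the kernel
   degenerates to bilinear per plane); out-of-field samples are 0.
6. **Pixel decoding**: each pixel's 16-value profile is rejected if its
   total is 0 or its contrast statistic — the second raw moment per unit
   brightness, `Σv²/Σv` (our concrete reading of "variance from zero
   normalised by total brightness"; threshold 1.0, configurable) — is too
   low; otherwise the pixel takes the used-or-unused code with the highest
   cosine similarity, if that score ≥ 0.7 (a flat profile scores
   `√(4/16) = 0.5` against any weight-4 code, so uniform noise cannot
   pass). Ties break to the lower code index.
7. **Calling**: 6-connected components of same-ID pixels are filtered by
   size ≥ 3, face-adjacent pairs ≥ 2, and ≥ 2 px extent in ≥ 2 of
   {x, y, z}; the transcript sits at the peak of the summed on-bit
   intensity and must coincide (within 1 px) with a raw local maximum in
   ≥ 75% of its on-bit images. The cosine fit at the called pixel is the
   spot score. Decoy calls are retained, flagged, and feed the
   specificity ratio used/(used+unused).

## Quantification and clustering

Containment is 2D (x, y), boundary-inclusive; a spot claimed by
overlapping polygons goes to the smaller cell (synthetic Voronoi cells
never overlap; imported segmentations may). QC drops cells with fewer
than 10 total transcripts; non-hepatocytes are cells with *any* count of
Lrat, Pecam1, Ptprc, Lyz2 or Adgre1. Note that with 2% background spots
this filter also removes the few percent of genuine hepatocytes hit by a
stray marker molecule — as it must, since "any expression" is the rule.

Normalisation scales each cell to the median total and stores the pre-log
values (used for fold changes) alongside `log1p` values (used for
clustering). Clustering restricts to the 16-gene marker panel, z-scores,
takes ≤10 principal components, builds a 15-NN graph and runs Leiden at
resolution 0.8 — calibrated once on synthetic control data to give 5–6
clusters. Clusters are annotated with the zone whose marker set has the
highest mean z-score.

**Cross-condition integration** is deliberate concatenation + *joint*
z-scoring. Anchor-based integration would remove the very composition
shift being measured; so would per-condition z-scoring, for a subtler
reason: a gene uniformly suppressed in the knockout is re-standardised
within that condition, resurrecting its gradient and hiding the loss.
Joint scaling preserves absolute differences; a per-condition option
exists for data with genuine global batch effects. Composition shifts are
tested per cluster with two-sided Fisher exact tests, BH-adjusted.

Leiden routinely splits even a statistically homogeneous population into
more than one community, so cluster *counts* are reported but never used
as a correctness criterion; what is asserted is that partitions separate
distinct populations (≥98% purity) and that zone annotations agree with
the generator's zone structure close to the per-cell noise ceiling.

## Axis profiling

A CV→PV axis plus the 500 px lateral extension defines a band divided
into 9 equal half-open segments (CV-side inclusive; a point at t = 1
exactly is outside). Density uses the full segment rectangle area; an
option to use cell-occupied area exists but is off by default. Profiles
are averaged across replicate regions (mean, SEM = sd/√n). Zone bands are
PC = S1–3, Mid = S4–6, PP = S7–9.

**Landmark auto-detection** (a convenience — manual axis annotations
reproduce the original drawn-line workflow and override it): smoothed
density maps of the CV landmark genes (Cyp2e1, Glul) and the PV landmark
gene (Sox9) provide mode candidates; each candidate is snapped to the
centroid of the nearest enclosed all-transcript void (≥3 bins of
25 px below 25% of the median tissue density) — a vein lumen contains no
transcripts at all, whereas pockets of dim non-hepatocyte cells retain
marker counts. Candidates are ranked by the landmark density in a
50–150 px ring around the void (the halo), and candidates below 0.8× the
best ring score are discarded. Each CV pairs with its nearest PV beyond
300 px.

**Differential expression** between conditions is computed per gene on
per-cell normalised (not log) hepatocyte expression: fold change
`(mean_B + ε)/(mean_A + ε)` with ε = 10⁻⁹, two-sided Wilcoxon rank-sum
p-values (chosen because per-cell tests produce p-values of the magnitude
such studies report; the original test is unnamed), BH adjustment across
genes. Pattern classification compares band-mean densities B/A per zone
band with a ±25% dead zone; bands empty in both conditions are
"unchanged". Named classes: "PC loss" (pericentral down without a
periportal gain) and "ectopic PC gain + PP {down, unchanged, up}".

## Problem sizes and determinism

Default benchmark sizes — 800 cells per region, 100 genes, 5 replicate
regions for profile recovery, 300 spots / 24 genes for decoding, ~500
hepatocytes per arm for differential recovery — were chosen so a full
desk run finishes in about a minute while keeping Poisson noise at levels
where the documented tolerances are meaningful. Profile-recovery checks
average across replicate regions exactly as the slide analysis averages
its 7–9 drawn regions; single regions leave low-rate (1.5/cell) genes at
correlations ≈ 0.85–0.90 from shot noise alone. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds and configurations reproduce byte-identical tables.

## Known limitations

* The decoder's robustness layers are tuned for in-plane drift; z-drift
  between rounds is not modelled or corrected.
* Specificity is the raw used/(used+unused) ratio; it is accurate when
  contamination resembles the decoy codes and will overestimate
  specificity when contamination preferentially matches used codes.
* The midzonal zone rests on a single marker (Pon1), so midzonal
  annotation is the least stable of the three zones — visible as
  boundary mixing in the zone-agreement tests.
* Landmark auto-detection assumes veins appear as enclosed transcript
  voids wrapped in landmark signal; heavily sectioned or edge-truncated
  veins require manual annotation.
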