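"""Synthetic liver-lobule generator.

Produces ground-truth datasets with the statistical structure the analysis
pipeline assumes: a field of tissue holding one or more central-vein (CV) /
portal-vein (PV) axis pairs, a Voronoi tessellation of cells (mostly
hepatocytes), per-cell transcript counts drawn from Poisson rates that
follow CV→PV zonation gradients, uniform background noise spots, and —
optionally — multi-round two-channel image stacks in which each transcript
appears as a Gaussian blob wherever its combinatorial code is "on", with
per-round rigid drift.

Coordinates are pixels: origin top-left, x rightward, y downward, 0-based;
z is the slice index of the imaging stack.

Three experimental scenarios are modelled:

``control``
    rates follow the unperturbed zonation profiles.
``dko``
    loss of endothelial Wnt ligands: pericentral Wnt-target genes are
    suppressed everywhere, and periportal genes gain an ectopic pericentral
    component while their native periportal expression falls, stays, or
    rises depending on a per-gene mode ("periportalization" of zone 3).
``agonist``
    systemic Wnt agonism: pericentral Wnt-target profiles are flattened
    toward their peak value across the whole axis (expansion into midzonal
    and periportal territory) while periportal genes are untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon, box

from .codebook import Codebook, ImagingConfig
from .rigid import RigidTransform

__all__ = [
    "LobuleGeometry",
    "Gene",
    "GenePanel",
    "ScenarioConfig",
    "default_panel",
    "default_scenario",
    "simulate_lobule",
    "zonation_intensity",
    "apply_scenario",
    "simulate_spots",
    "simulate_spot_field",
    "render_image_rounds",
    "MARKER_GENES",
    "NON_HEP_MARKERS",
]

ZONATION_CLASSES = ("pericentral", "midzonal", "periportal", "nonzonated")
CELL_CLASSES = ("hepatocyte", "endothelial", "stellate", "immune", "cholangiocyte")

#: the 16-gene zonated marker panel used for hepatocyte clustering
MARKER_GENES = {
    "pericentral": ("Cldn2", "Lect2", "Glul", "Oat", "Cyp1a2", "Cyp2e1", "Gstm1", "Rgn"),
    "midzonal": ("Pon1",),
    "periportal": ("Gls2", "G6pc", "Fbp1", "Hsd17b13", "Vtn", "Cyp2f2", "Pigr"),
}

#: markers whose expression flags a cell as non-hepatocyte
NON_HEP_MARKERS = ("Lrat", "Pecam1", "Ptprc", "Lyz2", "Adgre1")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass
class LobuleGeometry:
    """Field dimensions and vascular landmark positions (pixels)."""

    field_width: float = 3000.0
    field_height: float = 1800.0
    cv_centers: list[tuple[float, float]] = field(default_factory=lambda: [(500.0, 900.0)])
    pv_centers: list[tuple[float, float]] = field(default_factory=lambda: [(2500.0, 900.0)])
    vein_radius: float = 60.0

    def __post_init__(self) -> None:
        for p in list(self.cv_centers) + list(self.pv_centers):
            if not (0 <= p[0] <= self.field_width and 0 <= p[1] <= self.field_height):
                raise ValueError(f"vein center {p} lies outside the field")
        if not self.cv_centers or not self.pv_centers:
            raise ValueError("at least one CV-PV pair is required")
        for cv in self.cv_centers:
            d = min(math.dist(cv, pv) for pv in self.pv_centers)
            if d <= 4 * self.vein_radius:
                raise ValueError(
                    f"CV at {cv} has no PV farther than 4 x vein_radius "
                    f"({4 * self.vein_radius:.0f} px); field too small"
                )

    @property
    def axis_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Each CV paired with its nearest PV."""
        pairs = []
        for cv in self.cv_centers:
            pv = min(self.pv_centers, key=lambda p: math.dist(cv, p))
            pairs.append((np.asarray(cv, float), np.asarray(pv, float)))
        return pairs

    def axis_position(self, points: np.ndarray) -> np.ndarray:
        """Normalised lobule position t in [0, 1] for each point.

        t is the distance ratio between the two vascular poles of the
        nearest CV→PV pair, ``t = d_cv / (d_cv + d_pv)``: exactly 0 at the
        CV centre, exactly 1 at the PV centre, and concentric around each
        vein — matching the halo-like zonation of real lobules rather
        than a banded projection, which would plateau beyond the axis
        endpoints. The nearest pair is the one whose axis segment the
        point is closest to.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        best_t = np.zeros(len(pts))
        best_d = np.full(len(pts), np.inf)
        for cv, pv in self.axis_pairs:
            axis = pv - cv
            length = np.linalg.norm(axis)
            u = axis / length
            rel = pts - cv
            proj = np.clip(rel @ u / length, 0.0, 1.0)
            closest = cv + proj[:, None] * axis
            d = np.linalg.norm(pts - closest, axis=1)
            d_cv = np.linalg.norm(pts - cv, axis=1)
            d_pv = np.linalg.norm(pts - pv, axis=1)
            t = d_cv / (d_cv + d_pv)
            take = d < best_d
            best_t[take] = t[take]
            best_d[take] = d[take]
        return best_t if np.asarray(points).ndim == 2 else float(best_t[0])


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    """One panel entry: expression class and gradient shape parameters.

    ``base_rate`` is the expected transcript count per cell of the matching
    ``cell_class`` at the profile's peak. Shape parameters (all in axis
    units t ∈ [0, 1]):

    * ``decay_tau`` — e-folding scale of the pericentral exponential decay,
    * ``logistic_mid`` / ``logistic_scale`` — midpoint and steepness of the
      periportal logistic rise,
    * ``bump_center`` / ``bump_width`` — centre and s.d. of the midzonal
      Gaussian bump.
    """

    name: str
    zonation_class: str = "nonzonated"
    cell_class: str = "hepatocyte"
    base_rate: float = 3.0
    decay_tau: float = 0.30
    logistic_mid: float = 0.60
    logistic_scale: float = 0.12
    bump_center: float = 0.45
    bump_width: float = 0.13

    def __post_init__(self) -> None:
        if self.zonation_class not in ZONATION_CLASSES:
            raise ValueError(f"unknown zonation class {self.zonation_class!r}")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")


class GenePanel:
    """An ordered, name-unique collection of :class:`Gene` entries."""

    def __init__(self, genes: list[Gene]):
        names = [g.name for g in genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        self.genes = list(genes)
        self._by_name = {g.name: g for g in genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Gene:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def of_class(self, zonation_class: str) -> list[str]:
        return [g.name for g in self.genes if g.zonation_class == zonation_class]

    def hepatocyte_genes(self) -> list[str]:
        return [g.name for g in self.genes if g.cell_class == "hepatocyte"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.names,
                "zonation_class": [g.zonation_class for g in self.genes],
                "cell_class": [g.cell_class for g in self.genes],
                "base_rate": [g.base_rate for g in self.genes],
            }
        )


def default_panel(n_genes: int = 100) -> GenePanel:
    """The default ~100-gene panel.

    Named entries mirror the murine liver genes the pipeline's marker sets
    and scenarios refer to; the remainder are synthetic filler genes cycling
    through the zonation classes at a low rate, standing in for the rest of
    a 100-plex probe set.
    """
    marker_rate = 8.0
    genes: list[Gene] = []
    for cls, names in MARKER_GENES.items():
        for n in names:
            genes.append(Gene(n, cls, "hepatocyte", marker_rate))
    # additional zonated hepatocyte genes featured in the scenarios
    for n in ("Axin2", "Slc1a2", "Cyp27a1", "Tbx3"):
        genes.append(Gene(n, "pericentral", "hepatocyte", 5.0))
    for n in ("Pck1", "Arg1", "Ass1", "Cps1", "Fads1", "Elovl2", "Igf1", "C8b"):
        genes.append(Gene(n, "periportal", "hepatocyte", 5.0))
    for n in ("Ccnd1", "Igfbp2"):
        genes.append(Gene(n, "midzonal", "hepatocyte", 5.0))
    for n in ("Alb", "Ttr", "Apoa1"):
        genes.append(Gene(n, "nonzonated", "hepatocyte", 3.0))
    # non-hepatocyte cell-type markers
    genes.append(Gene("Lrat", "nonzonated", "stellate", 6.0))
    genes.append(Gene("Pecam1", "nonzonated", "endothelial", 6.0))
    genes.append(Gene("Ptprc", "nonzonated", "immune", 6.0))
    genes.append(Gene("Lyz2", "nonzonated", "immune", 6.0))
    genes.append(Gene("Adgre1", "nonzonated", "immune", 6.0))
    genes.append(Gene("Wnt2", "pericentral", "endothelial", 6.0))
    genes.append(Gene("Wnt9b", "pericentral", "endothelial", 6.0))
    genes.append(Gene("Sox9", "nonzonated", "cholangiocyte", 8.0))
    genes.append(Gene("Cldn7", "nonzonated", "cholangiocyte", 6.0))
    if n_genes < len(genes):
        genes = genes[:n_genes]
    fill_classes = ("pericentral", "periportal", "midzonal", "nonzonated")
    i = 0
    while len(genes) < n_genes:
        genes.append(Gene(f"Syn{i:03d}", fill_classes[i % 4], "hepatocyte", 1.5))
        i += 1
    return GenePanel(genes)


# ---------------------------------------------------------------------------
# zonation profiles and scenarios
# ---------------------------------------------------------------------------


def zonation_intensity(gene: Gene, t: float | np.ndarray) -> float | np.ndarray:
    """Expected transcript rate of ``gene`` at axis position ``t``.

    Pericentral genes decay exponentially from the CV, periportal genes
    rise logistically toward the PV, midzonal genes form a Gaussian bump
    around mid-axis, and nonzonated genes are flat.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr > 1)):
        raise ValueError("axis position t must lie in [0, 1]")
    cls = gene.zonation_class
    if cls == "pericentral":
        val = gene.base_rate * np.exp(-t_arr / gene.decay_tau)
    elif cls == "periportal":
        val = gene.base_rate / (1.0 + np.exp(-(t_arr - gene.logistic_mid) / gene.logistic_scale))
    elif cls == "midzonal":
        val = gene.base_rate * np.exp(-((t_arr - gene.bump_center) ** 2) / (2 * gene.bump_width**2))
    else:
        val = gene.base_rate * np.ones_like(t_arr)
    return val if np.asarray(t).ndim else float(val)


@dataclass
class ScenarioConfig:
    """Perturbation applied on top of the control zonation profiles.

    ``suppressed_genes`` is the pericentral Wnt-target set: multiplied by
    ``suppression_factor`` under ``dko``, flattened toward their peak under
    ``agonist`` (when ``agonist_expansion`` is set). ``ectopic_genes`` are
    periportal genes that, under ``dko``, gain an added pericentral
    component while their native periportal profile is scaled according to
    ``ectopic_mode`` (pp_decrease x0.5, pp_unchanged x1, pp_increase x1.5).
    """

    scenario: str = "control"
    suppressed_genes: frozenset[str] = frozenset()
    suppression_factor: float = 1.0
    ectopic_genes: frozenset[str] = frozenset()
    ectopic_mode: dict[str, str] = field(default_factory=dict)
    agonist_expansion: bool = False

    MODE_SCALE = {"pp_decrease": 0.5, "pp_unchanged": 1.0, "pp_increase": 1.5}

    def __post_init__(self) -> None:
        if self.scenario not in ("control", "dko", "agonist"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.suppression_factor < 0:
            raise ValueError("suppression_factor must be >= 0")
        if self.scenario == "control" and (
            self.suppressed_genes or self.ectopic_genes or self.agonist_expansion
        ):
            raise ValueError("control scenario must not carry modifiers")
        for g, m in self.ectopic_mode.items():
            if m not in self.MODE_SCALE:
                raise ValueError(f"unknown ectopic mode {m!r} for gene {g}")


def default_scenario(name: str, panel: GenePanel) -> ScenarioConfig:
    """Build the canonical configuration for each scenario on ``panel``.

    ``dko`` suppresses every pericentral hepatocyte gene to 15% and makes
    every periportal hepatocyte gene ectopically pericentral, with the
    periportal baseline falling for the Fads1-like set, rising for the
    urea-cycle-like set, and unchanged otherwise. ``agonist`` expands the
    pericentral Wnt-target profiles without touching periportal genes.
    """
    if name == "control":
        return ScenarioConfig("control")
    pc = frozenset(g for g in panel.of_class("pericentral") if panel[g].cell_class == "hepatocyte")
    pp = [g for g in panel.of_class("periportal") if panel[g].cell_class == "hepatocyte"]
    if name == "dko":
        pp_down = {"Fads1", "Elovl2"}
        pp_up = {"Ass1", "Arg1", "Pck1"}
        modes = {
            g: ("pp_decrease" if g in pp_down else "pp_increase" if g in pp_up else "pp_unchanged")
            for g in pp
        }
        return ScenarioConfig(
            "dko",
            suppressed_genes=pc,
            suppression_factor=0.15,
            ectopic_genes=frozenset(pp),
            ectopic_mode=modes,
        )
    if name == "agonist":
        return ScenarioConfig("agonist", suppressed_genes=pc, agonist_expansion=True)
    raise ValueError(f"unknown scenario {name!r}")


def apply_scenario(panel: GenePanel, scenario: ScenarioConfig | None = None):
    """Return ``rate(gene_name, t)`` — the scenario-modified intensity.

    Under ``control`` (or ``None``) the returned function is exactly
    :func:`zonation_intensity` on the panel entry.
    """
    scenario = scenario or ScenarioConfig("control")
    for g in set(scenario.suppressed_genes) | set(scenario.ectopic_genes):
        if g not in panel:
            raise ValueError(f"scenario refers to unknown gene {g!r}")

    def rate(gene_name: str, t):
        gene = panel[gene_name]
        base = zonation_intensity(gene, t)
        if scenario.scenario == "control":
            return base
        if scenario.scenario == "dko":
            if gene_name in scenario.suppressed_genes:
                return base * scenario.suppression_factor
            if gene_name in scenario.ectopic_genes:
                mode = scenario.ectopic_mode.get(gene_name, "pp_unchanged")
                scale = ScenarioConfig.MODE_SCALE[mode]
                t_arr = np.asarray(t, dtype=float)
                # truncated-shifted exponential: full gain at the CV, exactly
                # zero for t >= t0, so a pp_unchanged gene matches control
                # in the periportal territory
                t0, tau = 0.9, gene.decay_tau
                kernel = np.clip(
                    (np.exp(-t_arr / tau) - np.exp(-t0 / tau)) / (1 - np.exp(-t0 / tau)),
                    0.0, None,
                )
                out = scale * base + gene.base_rate * kernel
                return out if np.asarray(t).ndim else float(out)
            return base
        # agonist: flatten Wnt-target profiles toward their peak (t = 0)
        if scenario.agonist_expansion and gene_name in scenario.suppressed_genes:
            peak = zonation_intensity(gene, 0.0)
            out = np.full_like(np.asarray(t, dtype=float), peak)
            return out if np.asarray(t).ndim else float(peak)
        return base

    return rate


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------


def _hex_lattice(width: float, height: float, pitch: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice covering the field."""
    dy = pitch * math.sqrt(3) / 2
    rows = int(height / dy) + 2
    cols = int(width / pitch) + 2
    pts = []
    for r in range(rows):
        y = (r + 0.5) * dy
        x0 = pitch * (0.25 if r % 2 == 0 else 0.75)
        for c in range(cols):
            pts.append((x0 + c * pitch, y))
    pts = np.asarray(pts)
    pts += rng.uniform(-0.25, 0.25, size=pts.shape) * pitch
    keep = (
        (pts[:, 0] > 0) & (pts[:, 0] < width) & (pts[:, 1] > 0) & (pts[:, 1] < height)
    )
    return pts[keep]


def simulate_lobule(
    seed: int,
    geometry: LobuleGeometry | None = None,
    n_cells: int = 800,
    hepatocyte_fraction: float = 0.85,
) -> tuple[LobuleGeometry, pd.DataFrame]:
    """Tessellate the parenchyma into ``n_cells`` non-overlapping cells.

    Cells are Voronoi regions of a jittered hexagonal lattice, clipped to
    the field and excluding the vein lumens. Each cell carries its centroid,
    polygon, area, type (``hepatocyte_fraction`` hepatocytes by default,
    cholangiocytes seated next to portal veins) and ground-truth axis
    position ``t``.

    Returns ``(geometry, cells)`` where ``cells`` is a DataFrame with
    columns cell_id, x, y, area, cell_type, t, polygon; the lattice pitch
    used is stored in ``cells.attrs["lattice_pitch"]``.
    """
    geometry = geometry or LobuleGeometry()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    W, H = geometry.field_width, geometry.field_height
    veins = [Point(*c).buffer(geometry.vein_radius, quad_segs=24)
             for c in list(geometry.cv_centers) + list(geometry.pv_centers)]
    vein_area = sum(v.area for v in veins)
    usable = W * H - vein_area
    if usable <= 0:
        raise ValueError("field too small for the requested veins")
    # hexagonal packing: density = 2 / (sqrt(3) pitch^2)
    pitch = math.sqrt(2 * usable / (math.sqrt(3) * n_cells))
    vein_centers = np.array(list(geometry.cv_centers) + list(geometry.pv_centers), float)
    sites = None
    for _ in range(60):
        cand = _hex_lattice(W, H, pitch, rng)
        d = np.min(
            np.linalg.norm(cand[:, None, :] - vein_centers[None, :, :], axis=2), axis=1
        )
        cand = cand[d > geometry.vein_radius]
        if len(cand) >= n_cells:
            sites = cand
            break
        pitch *= 0.97
    if sites is None:
        raise ValueError("could not place the requested number of cells in the field")
    if len(sites) > n_cells:
        sites = sites[rng.choice(len(sites), n_cells, replace=False)]

    # mirror sites across the field edges so every Voronoi region is finite
    mirrored = [sites]
    for ref in (
        sites * [-1, 1],
        sites * [1, -1],
        np.column_stack([2 * W - sites[:, 0], sites[:, 1]]),
        np.column_stack([sites[:, 0], 2 * H - sites[:, 1]]),
    ):
        mirrored.append(ref)
    vor = Voronoi(np.vstack(mirrored))
    field_poly = box(0, 0, W, H)
    lumen = shapely.union_all(veins)
    polygons, centroids, areas = [], [], []
    for i in range(len(sites)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(field_poly).difference(lumen)
        if poly.geom_type == "MultiPolygon":  # vein arc can split a cell; keep the piece with the site
            site = Point(*sites[i])
            poly = min(poly.geoms, key=lambda g: g.distance(site))
        polygons.append(poly)
        c = poly.centroid
        centroids.append((c.x, c.y))
        areas.append(poly.area)
    centroids = np.asarray(centroids)
    t = geometry.axis_position(centroids)

    n_hep = int(round(hepatocyte_fraction * n_cells))
    n_non = n_cells - n_hep
    types = np.array(["hepatocyte"] * n_cells, dtype=object)
    # cholangiocytes form the bile ducts hugging the portal tract: take the
    # cells closest to a PV lumen
    pv = np.asarray(geometry.pv_centers, float)
    d_pv = np.min(np.linalg.norm(centroids[:, None, :] - pv[None, :, :], axis=2), axis=1)
    n_chol = max(1, int(0.1 * n_non)) if n_non else 0
    chol_idx = np.argsort(d_pv)[:n_chol]
    types[chol_idx] = "cholangiocyte"
    remaining = np.setdiff1d(np.arange(n_cells), chol_idx)
    rest = rng.choice(remaining, n_non - n_chol, replace=False)
    other = rng.choice(["endothelial", "stellate", "immune"], size=len(rest), p=[0.45, 0.2, 0.35])
    types[rest] = other

    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:04d}" for i in range(n_cells)],
            "x": centroids[:, 0],
            "y": centroids[:, 1],
            "area": areas,
            "cell_type": types,
            "t": t,
            "polygon": polygons,
        }
    )
    cells.attrs["lattice_pitch"] = pitch
    return geometry, cells


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------


def _points_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform samples inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(32, int((n - len(out)) * 4))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    return out[:n]


def simulate_spots(
    cells: pd.DataFrame,
    panel: GenePanel,
    scenario: ScenarioConfig | None = None,
    seed: int = 0,
    geometry: LobuleGeometry | None = None,
    background_fraction: float = 0.02,
    z_range: tuple[float, float] = (1.5, 5.5),
) -> tuple[pd.DataFrame, dict]:
    """Draw a decoded-transcript table from the lobule's zonation model.

    Per cell x gene, counts are Poisson with mean
    ``rate(gene, t_cell)`` under the scenario, and zero when the gene's
    cell class differs from the cell's type. Spot positions are uniform
    within the cell polygon; a ``background_fraction`` of all emitted spots
    is uniform over the field with random gene labels.

    Returns ``(spots, truth)``: spots has columns spot_id, x, y, z, gene,
    score; truth carries the per-spot source cell (``"background"`` for
    noise spots) and the cell table.
    """
    if len(panel) == 0:
        raise ValueError("empty gene panel")
    rng = np.random.default_rng(seed)
    rate = apply_scenario(panel, scenario)
    t_vals = cells["t"].to_numpy(float)
    types = cells["cell_type"].to_numpy()

    rates = np.zeros((len(cells), len(panel)))
    for j, gene in enumerate(panel):
        mask = types == gene.cell_class
        if mask.any():
            rates[mask, j] = rate(gene.name, t_vals[mask])
    counts = rng.poisson(rates)

    xs, ys, genes, src = [], [], [], []
    names = panel.names
    for i, (poly, row_counts) in enumerate(zip(cells["polygon"], counts)):
        n_i = int(row_counts.sum())
        if n_i == 0:
            continue
        pts = _points_in_polygon(poly, n_i, rng)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        genes.append(np.repeat(names, row_counts))
        src.append(np.repeat(cells["cell_id"].iloc[i], n_i))
    n_real = int(counts.sum())
    if background_fraction > 0 and n_real > 0:
        if geometry is None:
            W = float(cells["x"].max() + cells["x"].min())
            H = float(cells["y"].max() + cells["y"].min())
        else:
            W, H = geometry.field_width, geometry.field_height
        n_bg = int(round(n_real * background_fraction / (1 - background_fraction)))
        xs.append(rng.uniform(0, W, n_bg))
        ys.append(rng.uniform(0, H, n_bg))
        genes.append(rng.choice(names, n_bg))
        src.append(np.repeat("background", n_bg))
    if not xs:
        spots = pd.DataFrame(columns=["spot_id", "x", "y", "z", "gene", "score"])
        truth = {"spots": pd.DataFrame(columns=["spot_id", "gene", "cell_id"]), "cells": cells}
        return spots, truth
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    gene_col = np.concatenate(genes)
    src_col = np.concatenate(src)
    z = rng.uniform(z_range[0], z_range[1], len(x))
    spots = pd.DataFrame(
        {
            "spot_id": [f"spot_{i:06d}" for i in range(len(x))],
            "x": x,
            "y": y,
            "z": z,
            "gene": gene_col,
            "score": 1.0,
        }
    )
    truth_spots = pd.DataFrame(
        {"spot_id": spots["spot_id"], "gene": gene_col, "cell_id": src_col}
    )
    truth = {"spots": truth_spots, "cells": cells, "counts": counts}
    return spots, truth


def simulate_spot_field(
    n_spots: int,
    genes: list[str],
    field_shape: tuple[float, float] = (192.0, 192.0),
    min_separation: float = 6.0,
    margin: float = 12.0,
    z_range: tuple[float, float] = (1.5, 5.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform, well-separated spots for decoder fixtures.

    Dart-throwing with a minimum pairwise distance so rendered blobs stay
    resolvable; genes drawn uniformly from ``genes``.
    """
    rng = np.random.default_rng(seed)
    W, H = field_shape
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n_spots:
        p = (rng.uniform(margin, W - margin), rng.uniform(margin, H - margin))
        if not pts or cKDTree(np.asarray(pts)).query(p)[0] >= min_separation:
            pts.append(p)
        tries += 1
        if tries > 200 * n_spots:
            raise ValueError("field too crowded for the requested spot separation")
    arr = np.asarray(pts)
    return pd.DataFrame(
        {
            "spot_id": [f"spot_{i:06d}" for i in range(n_spots)],
            "x": arr[:, 0],
            "y": arr[:, 1],
            "z": rng.uniform(z_range[0], z_range[1], n_spots),
            "gene": rng.choice(genes, n_spots),
            "score": 1.0,
        }
    )


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


@dataclass
class RenderParams:
    """Optics and drift parameters for rendering encoded image stacks."""

    field_shape: tuple[int, int] = (192, 192)  # (height, width) px
    amplitude: float = 100.0
    amplitude_jitter: float = 0.2  # uniform +/- fraction per spot
    sigma_xy: float = 1.0  # blob s.d., px
    sigma_z: float = 0.8  # blob s.d., slices
    background_level: float = 0.0
    noise_sd: float = 0.0
    max_drift_deg: float = 3.0
    max_drift_px: float = 5.0


def render_image_rounds(
    spots: pd.DataFrame,
    codebook: Codebook,
    imaging: ImagingConfig | None = None,
    params: RenderParams | None = None,
    seed: int = 0,
    transforms: list[RigidTransform] | None = None,
) -> tuple[dict[tuple[int, int], np.ndarray], list[RigidTransform], dict]:
    """Render one 3D stack per round x channel with per-round rigid drift.

    Each spot contributes an isotropic Gaussian blob to stack (r, c) iff
    its code bit (r, c) is 1. Round 1 is the reference (identity); later
    rounds get a random rotation + translation (bounded by the params)
    unless explicit ``transforms`` are supplied. Spots that drift outside
    the field are clipped; the count is reported in the returned log.

    Returns ``(stacks, transforms, log)`` with stacks keyed by 0-based
    (round, channel), shape (z, y, x), dtype float32.
    """
    imaging = imaging or ImagingConfig()
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    for g in spots["gene"].unique():
        if g not in codebook.codes:
            raise ValueError(f"spot gene {g!r} has no code in the codebook")
    H, W = params.field_shape
    Z = imaging.z_slices
    center = (W / 2.0, H / 2.0)
    if transforms is None:
        transforms = [RigidTransform.identity()]
        for _ in range(1, imaging.rounds):
            ang = np.deg2rad(rng.uniform(-params.max_drift_deg, params.max_drift_deg))
            shift = rng.uniform(-params.max_drift_px, params.max_drift_px, 2)
            transforms.append(
                RigidTransform.from_center_rotation(ang, (shift[0], shift[1]), center)
            )
    elif len(transforms) != imaging.rounds:
        raise ValueError("need one transform per round")

    amp = params.amplitude * (
        1 + rng.uniform(-params.amplitude_jitter, params.amplitude_jitter, len(spots))
    )
    xyz = spots[["x", "y", "z"]].to_numpy(float)
    codes = np.zeros((len(spots), codebook.n_bits), dtype=bool)
    for i, g in enumerate(spots["gene"]):
        codes[i] = codebook.codes[g]

    rx = int(math.ceil(4 * params.sigma_xy))
    rz = int(math.ceil(3 * params.sigma_z))
    n_clipped = 0
    stacks: dict[tuple[int, int], np.ndarray] = {}
    for r in range(imaging.rounds):
        moved = transforms[r].apply(xyz[:, :2]) if len(spots) else np.empty((0, 2))
        for c in range(imaging.channels):
            stack = np.zeros((Z, H, W), dtype=np.float64)
            bit = r * imaging.channels + c
            for i in np.nonzero(codes[:, bit])[0]:
                x, y = moved[i]
                z = xyz[i, 2]
                if not (0 <= x < W and 0 <= y < H):
                    n_clipped += 1
                    continue
                x0, x1 = max(0, int(x) - rx), min(W, int(x) + rx + 1)
                y0, y1 = max(0, int(y) - rx), min(H, int(y) + rx + 1)
                z0, z1 = max(0, int(z) - rz), min(Z, int(z) + rz + 1)
                zz, yy, xx = np.meshgrid(
                    np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
                )
                blob = amp[i] * np.exp(
                    -((xx - x) ** 2 + (yy - y) ** 2) / (2 * params.sigma_xy**2)
                    - (zz - z) ** 2 / (2 * params.sigma_z**2)
                )
                stack[z0:z1, y0:y1, x0:x1] += blob
            stack += params.background_level
            if params.noise_sd > 0:
                stack += rng.normal(0, params.noise_sd, stack.shape)
                np.clip(stack, 0, None, out=stack)
            stacks[(r, c)] = stack.astype(np.float32)
    if n_clipped:
        warnings.warn(f"{n_clipped} spot renderings clipped outside the field")
    log = {"n_clipped": n_clipped, "n_spots": len(spots)}
    return stacks, transforms, log
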