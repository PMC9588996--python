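"""Lobule generator: geometry, gradients, scenarios, spot sampling, rendering."""

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.spatial import cKDTree

from lobulemap.codebook import ImagingConfig
from lobulemap.synthetic import (
    Gene,
    LobuleGeometry,
    RenderParams,
    ScenarioConfig,
    apply_scenario,
    default_panel,
    default_scenario,
    render_image_rounds,
    simulate_lobule,
    simulate_spots,
    zonation_intensity,
)


class TestGeometry:
    def test_axis_position_endpoints(self):
        geo = LobuleGeometry()
        assert geo.axis_position(np.array(geo.cv_centers[0])) == pytest.approx(0.0)
        assert geo.axis_position(np.array(geo.pv_centers[0])) == pytest.approx(1.0)

    def test_vein_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            LobuleGeometry(100, 100, [(500, 50)], [(50, 50)], 5)

    def test_cv_pv_too_close_rejected(self):
        with pytest.raises(ValueError, match="4 x vein_radius"):
            LobuleGeometry(1000, 1000, [(500, 500)], [(600, 500)], 60)


class TestSimulateLobule:
    def test_requested_cell_count_and_determinism(self):
        geo1, cells1 = simulate_lobule(1, n_cells=300)
        geo2, cells2 = simulate_lobule(1, n_cells=300)
        assert len(cells1) == 300
        pd.testing.assert_frame_equal(
            cells1.drop(columns="polygon"), cells2.drop(columns="polygon")
        )

    def test_cells_do_not_overlap(self, lobule):
        cells = lobule["cells"]
        polys = list(cells["polygon"])[:80]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                inter = polys[i].intersection(polys[j]).area
                assert inter < 1e-6 * max(polys[i].area, polys[j].area)

    def test_mean_neighbor_spacing_close_to_pitch(self, lobule):
        cells = lobule["cells"]
        pts = cells[["x", "y"]].to_numpy()
        d, _ = cKDTree(pts).query(pts, k=2)
        pitch = cells.attrs["lattice_pitch"]
        assert d[:, 1].mean() == pytest.approx(pitch, rel=0.15)

    def test_hepatocyte_fraction(self, lobule):
        frac = (lobule["cells"]["cell_type"] == "hepatocyte").mean()
        assert frac == pytest.approx(0.85, abs=0.01)

    def test_nonpositive_cell_count_raises(self):
        with pytest.raises(ValueError):
            simulate_lobule(0, n_cells=0)


class TestZonationIntensity:
    def test_nonzonated_constant(self):
        g = Gene("x", "nonzonated", base_rate=3.0)
        for t in (0.0, 0.3, 1.0):
            assert zonation_intensity(g, t) == pytest.approx(3.0)

    def test_pericentral_decreasing(self):
        g = Gene("x", "pericentral", base_rate=8.0)
        assert zonation_intensity(g, 0.0) > zonation_intensity(g, 1.0)
        vals = zonation_intensity(g, np.linspace(0, 1, 50))
        assert np.all(np.diff(vals) < 0)

    def test_periportal_increasing(self):
        g = Gene("x", "periportal", base_rate=8.0)
        vals = zonation_intensity(g, np.linspace(0, 1, 50))
        assert np.all(np.diff(vals) > 0)

    def test_midzonal_argmax_in_mid_band(self):
        g = Gene("x", "midzonal", base_rate=8.0)
        grid = np.linspace(0, 1, 101)
        t_star = grid[np.argmax(zonation_intensity(g, grid))]
        assert 0.35 <= t_star <= 0.55

    def test_domain_error(self):
        with pytest.raises(ValueError):
            zonation_intensity(Gene("x"), 1.2)


class TestScenarios:
    def test_control_identity(self, panel):
        rate = apply_scenario(panel, ScenarioConfig("control"))
        t = np.linspace(0, 1, 11)
        for g in ("Glul", "Gls2", "Pon1", "Alb"):
            np.testing.assert_allclose(rate(g, t), zonation_intensity(panel[g], t))

    def test_dko_pp_unchanged_matches_control_periportally(self, panel):
        scen = default_scenario("dko", panel)
        rate = apply_scenario(panel, scen)
        assert scen.ectopic_mode["Gls2"] == "pp_unchanged"
        assert rate("Gls2", 0.95) == pytest.approx(zonation_intensity(panel["Gls2"], 0.95))

    def test_dko_suppression_scales_everywhere(self, panel):
        scen = default_scenario("dko", panel)
        rate = apply_scenario(panel, scen)
        t = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            rate("Glul", t), 0.15 * zonation_intensity(panel["Glul"], t)
        )

    def test_agonist_leaves_periportal_genes_untouched(self, panel):
        rate = apply_scenario(panel, default_scenario("agonist", panel))
        t = np.linspace(0, 1, 11)
        for g in ("Gls2", "Cyp2f2", "Pigr"):
            np.testing.assert_allclose(rate(g, t), zonation_intensity(panel[g], t))

    def test_agonist_flattens_wnt_targets_high(self, panel):
        rate = apply_scenario(panel, default_scenario("agonist", panel))
        vals = rate("Cyp2e1", np.linspace(0, 1, 11))
        assert np.allclose(vals, panel["Cyp2e1"].base_rate)

    def test_unknown_gene_in_modifiers_rejected(self, panel):
        with pytest.raises(ValueError, match="unknown gene"):
            apply_scenario(
                panel,
                ScenarioConfig("dko", suppressed_genes=frozenset({"NotAGene"}),
                               suppression_factor=0.5),
            )

    def test_control_with_modifiers_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig("control", suppressed_genes=frozenset({"Glul"}))


class TestSimulateSpots:
    def test_determinism_byte_identical(self, panel, lobule):
        geo, cells = lobule["geometry"], lobule["cells"]
        s1, _ = simulate_spots(cells, panel, seed=9, geometry=geo)
        s2, _ = simulate_spots(cells, panel, seed=9, geometry=geo)
        assert s1.to_csv() == s2.to_csv()

    def test_spot_conservation(self, panel, lobule):
        spots, truth = lobule["spots"], lobule["truth"]
        n_bg = (truth["spots"]["cell_id"] == "background").sum()
        assert len(spots) == truth["counts"].sum() + n_bg
        assert n_bg == pytest.approx(0.02 * len(spots), rel=0.05)

    def test_spots_inside_their_cell(self, panel, lobule):
        spots, truth, cells = lobule["spots"], lobule["truth"], lobule["cells"]
        merged = spots.merge(truth["spots"][["spot_id", "cell_id"]], on="spot_id")
        merged = merged[merged["cell_id"] != "background"].sample(500, random_state=0)
        poly_by_id = dict(zip(cells["cell_id"], cells["polygon"]))
        for _, row in merged.iterrows():
            # boundary-inclusive: sampled interior points always covered
            assert shapely.contains_xy(
                poly_by_id[row["cell_id"]].buffer(1e-6), row["x"], row["y"]
            )

    def test_zero_suppression_removes_gene_from_hepatocytes(self, panel, lobule):
        geo, cells = lobule["geometry"], lobule["cells"]
        scen = ScenarioConfig(
            "dko", suppressed_genes=frozenset({"Glul"}), suppression_factor=0.0
        )
        spots, truth = simulate_spots(cells, panel, scen, seed=4, geometry=geo)
        merged = truth["spots"]
        real_glul = merged[(merged["gene"] == "Glul") & (merged["cell_id"] != "background")]
        assert len(real_glul) == 0

    def test_poisson_total_matches_expectation(self, panel, lobule):
        """Over 10 seeds, total spot count of a gene ≈ summed per-cell rate."""
        geo, cells = lobule["geometry"], lobule["cells"]
        gene = panel["Glul"]
        hep = cells[cells["cell_type"] == "hepatocyte"]
        expected = zonation_intensity(gene, hep["t"].to_numpy()).sum()
        totals = []
        for seed in range(10):
            _, truth = simulate_spots(
                cells, panel, seed=seed, geometry=geo, background_fraction=0.0
            )
            j = panel.names.index("Glul")
            totals.append(truth["counts"][:, j].sum())
        assert abs(np.mean(totals) - expected) < 3 * np.sqrt(expected)

    def test_dko_reduces_suppressed_counts_by_factor(self, panel, lobule):
        geo, cells = lobule["geometry"], lobule["cells"]
        scen = default_scenario("dko", panel)
        _, truth_c = simulate_spots(cells, panel, seed=5, geometry=geo,
                                    background_fraction=0.0)
        _, truth_d = simulate_spots(cells, panel, scen, seed=5, geometry=geo,
                                    background_fraction=0.0)
        j = panel.names.index("Cyp2e1")
        ratio = truth_d["counts"][:, j].sum() / truth_c["counts"][:, j].sum()
        assert ratio == pytest.approx(0.15, abs=0.15 * 0.10 + 0.02)

    def test_gradient_nonincreasing_over_t_bins(self, panel, lobule):
        cells, truth = lobule["cells"], lobule["truth"]
        hep = cells["cell_type"].to_numpy() == "hepatocyte"
        t = cells["t"].to_numpy()[hep]
        j = panel.names.index("Glul")
        counts = truth["counts"][hep, j]
        bins = np.clip((t * 9).astype(int), 0, 8)
        means = np.array([counts[bins == b].mean() for b in range(9)])
        assert (np.diff(means) > 0).sum() <= 1

    def test_empty_panel_rejected(self, lobule):
        from lobulemap.synthetic import GenePanel

        with pytest.raises(ValueError, match="empty"):
            simulate_spots(lobule["cells"], GenePanel([]), seed=0)


class TestRenderImageRounds:
    def test_sixteen_stacks_for_default_config(self, rendered_field):
        assert len(rendered_field["stacks"]) == 16
        assert all(s.shape == (8, 192, 192) for s in rendered_field["stacks"].values())

    def test_round_one_is_reference(self, rendered_field):
        assert rendered_field["transforms"][0].is_identity()

    def test_zero_spots_background_only(self, codebook24):
        spots = pd.DataFrame(columns=["spot_id", "x", "y", "z", "gene", "score"])
        params = RenderParams(background_level=2.0)
        stacks, _, _ = render_image_rounds(spots, codebook24, params=params, seed=0)
        assert all(np.allclose(s, 2.0) for s in stacks.values())

    def test_single_spot_centroid_within_quarter_pixel(self, codebook24):
        gene = codebook24.genes[0]
        spots = pd.DataFrame(
            {"spot_id": ["s0"], "x": [96.3], "y": [100.7], "z": [4.0],
             "gene": [gene], "score": [1.0]}
        )
        transforms = [__import__("lobulemap.rigid", fromlist=["RigidTransform"])
                      .RigidTransform.identity()] * 8
        params = RenderParams(amplitude_jitter=0.0)
        stacks, _, _ = render_image_rounds(
            spots, codebook24, params=params, seed=0, transforms=transforms
        )
        code = codebook24.codes[gene]
        for bit in np.nonzero(code)[0]:
            r, c = divmod(int(bit), 2)
            s = stacks[(r, c)].sum(axis=0)
            yy, xx = np.mgrid[0 : s.shape[0], 0 : s.shape[1]]
            cx = (xx * s).sum() / s.sum()
            cy = (yy * s).sum() / s.sum()
            assert abs(cx - 96.3) < 0.25 and abs(cy - 100.7) < 0.25

    def test_unknown_gene_rejected(self, codebook24):
        spots = pd.DataFrame(
            {"spot_id": ["s0"], "x": [50.0], "y": [50.0], "z": [4.0],
             "gene": ["NotInCodebook"], "score": [1.0]}
        )
        with pytest.raises(ValueError, match="no code"):
            render_image_rounds(spots, codebook24, seed=0)
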