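"""Signal segmentation and decoding: each stage plus the end-to-end path."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from lobulemap.codebook import build_codebook
from lobulemap.decoder import (
    DecoderParams,
    apply_rigid,
    call_transcripts,
    correct_background,
    decode_experiment,
    decode_pixels,
    detect_maxima,
    estimate_specificity,
    form_zgroups,
    icp_align,
    maxima_target,
)
from lobulemap.rigid import RigidTransform
from lobulemap.synthetic import RenderParams, render_image_rounds, simulate_spot_field


def _gaussian_blob(shape, x, y, z, amp=100.0, sxy=1.0, sz=0.8):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sxy**2) - (zz - z) ** 2 / (2 * sz**2)
    )


class TestCorrectBackground:
    def test_constant_image_becomes_zero(self):
        out = correct_background(np.full((3, 32, 32), 7.0))
        assert np.allclose(out, 0.0)

    def test_all_zero_stays_zero(self):
        assert np.allclose(correct_background(np.zeros((2, 16, 16))), 0.0)

    def test_blob_peak_preserved_over_offset(self):
        blob = _gaussian_blob((5, 64, 64), 32, 32, 2)
        corrected = correct_background(blob + 50.0)
        peak_ref = correct_background(blob).max()
        assert corrected.max() == pytest.approx(peak_ref, rel=0.10)


class TestDetectMaxima:
    def test_target_value_is_area_times_factor(self):
        assert maxima_target(1000.0, 0.5) == 500.0

    def test_flat_image_no_maxima(self):
        assert len(detect_maxima(np.zeros((3, 32, 32)))) == 0

    def test_three_isolated_blobs_found_at_peaks(self):
        stack = np.zeros((5, 64, 64))
        truth = [(10, 12, 2), (40, 50, 2), (55, 20, 2)]
        for x, y, z in truth:
            stack += _gaussian_blob(stack.shape, x, y, z)
        maxima = detect_maxima(stack)
        planes = maxima[maxima["z"] == 2]
        found = set(zip(planes["x"], planes["y"]))
        for x, y, _ in truth:
            assert (x, y) in found

    def test_threshold_calibration_approaches_target(self):
        # dense noise so candidates far exceed the target; use a tiny pixel
        # size so the per-plane target is small
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 1, (4, 64, 64))
        params = DecoderParams()
        target = 4 * maxima_target(64 * 64 * 0.05**2, params.maxima_area_factor)
        kept = detect_maxima(stack, params, pixel_size=0.05)
        assert len(kept) <= 1.15 * target


class TestZGroups:
    def test_isolated_maximum_excluded(self):
        m = pd.DataFrame({"x": [10], "y": [10], "z": [2], "babs": [5.0],
                          "bback": [0.0], "bperi": [0.0]})
        groups, reps = form_zgroups(m)
        assert groups == [] and len(reps) == 0

    def test_adjacent_pair_representative_is_brightest(self):
        m = pd.DataFrame({"x": [10, 10], "y": [7, 7], "z": [3, 4],
                          "babs": [10.0, 12.0], "bback": 0.0, "bperi": 0.0})
        groups, reps = form_zgroups(m)
        assert len(groups) == 1
        assert reps.iloc[0]["z"] == 4 and reps.iloc[0]["babs"] == 12.0

    def test_chain_counts_as_single_hit(self):
        m = pd.DataFrame({"x": 20, "y": 20, "z": [1, 2, 3, 4],
                          "babs": [1.0, 2.0, 3.0, 2.5], "bback": 0.0, "bperi": 0.0})
        groups, reps = form_zgroups(m)
        assert len(groups) == 1 and len(groups[0]) == 4

    def test_grouping_matches_bfs_oracle(self):
        """Random maxima: group membership equals a brute-force BFS on the
        adjacent-slice-within-radius graph."""
        rng = np.random.default_rng(42)
        n = 120
        m = pd.DataFrame({
            "x": rng.uniform(0, 60, n), "y": rng.uniform(0, 60, n),
            "z": rng.integers(0, 6, n), "babs": rng.uniform(1, 10, n),
            "bback": 0.0, "bperi": 0.0,
        })
        groups, _ = form_zgroups(m, radius=2.5)
        # oracle: BFS over explicit pairwise adjacency
        adj = [[] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i != j and abs(m.z[i] - m.z[j]) == 1 and np.hypot(
                    m.x[i] - m.x[j], m.y[i] - m.y[j]
                ) <= 2.5:
                    adj[i].append(j)
        seen, comps = set(), []
        for s in range(n):
            if s in seen:
                continue
            comp, stack = set(), [s]
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u])
            seen |= comp
            if len(comp) >= 2:
                comps.append(frozenset(comp))
        got = {frozenset(g.index) for g in groups}
        assert got == set(comps)


class TestIcp:
    def test_identical_clouds_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (50, 2))
        res = icp_align(pts, pts)
        assert abs(res.transform.angle) < 1e-9
        assert np.hypot(*res.transform.translation) < 1e-9

    def test_known_transform_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 200, (200, 2))
        true = RigidTransform.from_center_rotation(
            np.deg2rad(3.0), (4.0, -2.0), (100, 100)
        )
        res = icp_align(true.inverse().apply(ref), ref)
        assert abs(np.rad2deg(res.transform.angle - true.angle)) < 0.1
        assert np.hypot(
            *(np.array(res.transform.translation) - np.array(true.translation))
        ) < 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_robust_to_spurious_points(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0, 200, (200, 2))
        true = RigidTransform.from_center_rotation(
            np.deg2rad(rng.uniform(-5, 5)), rng.uniform(-10, 10, 2), (100, 100)
        )
        cloud = np.vstack([true.inverse().apply(ref), rng.uniform(0, 200, (20, 2))])
        res = icp_align(cloud, ref, trim=0.8)
        assert abs(np.rad2deg(res.transform.angle - true.angle)) < 0.5
        assert np.hypot(
            *(np.array(res.transform.translation) - np.array(true.translation))
        ) < 0.5

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            icp_align(np.zeros((2, 2)), np.zeros((5, 2)))


class TestApplyRigid:
    def test_identity_on_stack(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 1, (3, 16, 16))
        np.testing.assert_allclose(apply_rigid(stack, RigidTransform.identity()), stack)

    def test_integer_translation_matches_shift_oracle(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 1, (2, 24, 24))
        out = apply_rigid(stack, RigidTransform(0.0, (3.0, 5.0)))
        expected = np.zeros_like(stack)
        expected[:, 5:, 3:] = stack[:, :-5, :-3]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_cloud_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (40, 2))
        tr = RigidTransform.from_center_rotation(0.3, (5, -7), (50, 50))
        back = tr.inverse().apply(tr.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestDecodePixels:
    def test_exact_code_profile_assigned_score_one(self, codebook24):
        gene = codebook24.genes[3]
        code = codebook24.codes[gene]
        stacks = [np.full((1, 2, 2), 10.0 * b) for b in code]
        id_map, score = decode_pixels(stacks, codebook24,
                                      DecoderParams(profile_variance_threshold=0.0))
        assert np.all(id_map == 3)
        assert np.allclose(score, 1.0)

    def test_all_zero_profile_unassigned(self, codebook24):
        stacks = [np.zeros((1, 2, 2))] * 16
        id_map, _ = decode_pixels(stacks, codebook24)
        assert np.all(id_map == -1)

    def test_uniform_profile_below_min_score(self, codebook24):
        # cosine of a flat profile against any weight-4 code is sqrt(4/16) = 0.5
        stacks = [np.full((1, 2, 2), 5.0)] * 16
        id_map, _ = decode_pixels(stacks, codebook24,
                                  DecoderParams(profile_variance_threshold=0.0))
        assert np.all(id_map == -1)

    def test_gene_order_permutation_equivariant(self, codebook24):
        from lobulemap.codebook import Codebook

        gene = codebook24.genes[5]
        code = codebook24.codes[gene]
        stacks = [np.full((1, 2, 2), 8.0 * b) for b in code]
        perm = list(reversed(codebook24.genes))
        cb2 = Codebook(codebook24.rounds, codebook24.channels,
                       {g: codebook24.codes[g] for g in perm},
                       codebook24.unused, codebook24.weight, codebook24.min_distance)
        p = DecoderParams(profile_variance_threshold=0.0)
        id1, _ = decode_pixels(stacks, codebook24, p)
        id2, _ = decode_pixels(stacks, cb2, p)
        _, labels1, _ = codebook24.all_codes()
        _, labels2, _ = cb2.all_codes()
        assert labels1[id1[0, 0, 0]] == labels2[id2[0, 0, 0]] == gene

    def test_stack_count_mismatch_rejected(self, codebook24):
        with pytest.raises(ValueError, match="stacks"):
            decode_pixels([np.zeros((1, 2, 2))] * 15, codebook24)


class TestCallTranscripts:
    def test_single_pixel_group_filtered(self, codebook24):
        id_map = np.full((4, 8, 8), -1, dtype=np.int32)
        id_map[2, 4, 4] = 0
        stacks = [np.ones((4, 8, 8))] * 16
        spots = call_transcripts(id_map, stacks, codebook24)
        assert len(spots) == 0

    def test_rendered_single_spot_called_within_one_pixel(self, codebook24):
        gene = codebook24.genes[0]
        spots_in = pd.DataFrame(
            {"spot_id": ["s0"], "x": [40.2], "y": [33.8], "z": [4.0],
             "gene": [gene], "score": [1.0]}
        )
        transforms = [RigidTransform.identity()] * 8
        stacks, _, _ = render_image_rounds(
            spots_in, codebook24, params=RenderParams(field_shape=(80, 80),
                                                      amplitude_jitter=0.0),
            seed=0, transforms=transforms,
        )
        res = decode_experiment(stacks, codebook24)
        called = res.spots[res.spots["used"]]
        assert len(called) == 1
        assert called.iloc[0]["gene"] == gene
        assert np.hypot(called.iloc[0]["x"] - 40.2, called.iloc[0]["y"] - 33.8) <= 1.0

    def test_two_spots_two_genes(self, codebook24):
        g1, g2 = codebook24.genes[1], codebook24.genes[2]
        spots_in = pd.DataFrame(
            {"spot_id": ["a", "b"], "x": [30.0, 40.0], "y": [30.0, 30.0],
             "z": [4.0, 4.0], "gene": [g1, g2], "score": 1.0}
        )
        transforms = [RigidTransform.identity()] * 8
        stacks, _, _ = render_image_rounds(
            spots_in, codebook24, params=RenderParams(field_shape=(64, 64),
                                                      amplitude_jitter=0.0),
            seed=0, transforms=transforms,
        )
        res = decode_experiment(stacks, codebook24)
        called = res.spots[res.spots["used"]].sort_values("x")
        assert list(called["gene"]) == [g1, g2]


class TestSpecificity:
    def test_all_used_calls(self, codebook24):
        spots = pd.DataFrame({"gene": [codebook24.genes[0]] * 10})
        qc = estimate_specificity(spots, codebook24)
        assert qc.specificity_estimate == 1.0

    def test_ratio_definition(self, codebook24):
        spots = pd.DataFrame({"gene": [codebook24.genes[0]] * 90 + ["unused_0"] * 10})
        qc = estimate_specificity(spots, codebook24)
        assert qc.specificity_estimate == pytest.approx(0.9)
        assert (qc.n_used_matches, qc.n_unused_matches) == (90, 10)

    def test_zero_calls_flagged(self, codebook24):
        qc = estimate_specificity(pd.DataFrame({"gene": []}), codebook24)
        assert qc.flagged and qc.specificity_estimate is None


class TestEndToEnd:
    def test_recall_precision_and_idempotence(self, codebook24, rendered_field):
        spots_true = rendered_field["spots"]
        res = decode_experiment(rendered_field["stacks"], codebook24)
        called = res.spots[res.spots["used"]]
        tree = cKDTree(spots_true[["x", "y"]].to_numpy(float))
        d, idx = tree.query(called[["x", "y"]].to_numpy(float))
        ok = (d <= 1.5) & (
            called["gene"].to_numpy() == spots_true["gene"].to_numpy()[idx]
        )
        precision = ok.mean()
        recall = len(set(idx[ok])) / len(spots_true)
        assert precision >= 0.95 and recall >= 0.95
        # idempotence: decoding the same stacks again gives an identical table
        res2 = decode_experiment(rendered_field["stacks"], codebook24)
        pd.testing.assert_frame_equal(res.spots, res2.spots)

    def test_empty_stacks_empty_table(self, codebook24):
        stacks = {(r, c): np.zeros((4, 32, 32)) for r in range(8) for c in range(2)}
        res = decode_experiment(stacks, codebook24)
        assert len(res.spots) == 0
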