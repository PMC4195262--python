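import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import icextract as ic
from icextract.fusion import (
    Patch,
    adaptive_h,
    bilateral_weight,
    block_center_grid,
    blockwise_fusion,
    classical_weight,
    extract_patch,
    patch_distance,
    structural_similarity,
    threshold_votes,
    voxelwise_fusion,
)
from conftest import naive_voxelwise_fusion


def patch_at(values, center=(0, 0, 0)):
    return Patch.from_values(np.asarray(values, dtype=float), center)


def flat_patch(mean, std, n=27, center=(0, 0, 0)):
    """Patch with exactly the requested mean and std (two-level values)."""
    half = n // 2
    v = np.concatenate([np.full(half, -1.0), np.full(n - half, half / (n - half))])
    v = v / v.std() * std + mean
    return patch_at(v, center)


class TestStructuralSimilarity:
    def test_identical_patch_scores_one(self):
        p = patch_at([1, 2, 3, 4, 5])
        assert structural_similarity(p, p) == pytest.approx(1.0)

    def test_mean_ratio_term_evaluates_directly(self):
        p = flat_patch(100.0, 10.0)
        q = flat_patch(200.0, 10.0)
        assert structural_similarity(p, q) == pytest.approx(0.8, abs=1e-12)

    def test_single_zero_std_gives_zero(self):
        p = flat_patch(100.0, 0.0)
        q = flat_patch(100.0, 5.0)
        assert structural_similarity(p, q) == 0.0

    def test_both_zero_std_gives_mean_term_only(self):
        p = patch_at(np.full(27, 80.0))
        assert structural_similarity(p, p) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_score_lies_in_unit_interval_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        p = patch_at(rng.uniform(0, 300, 27))
        q = patch_at(rng.uniform(0, 300, 27))
        s = structural_similarity(p, q)
        assert 0.0 <= s <= 1.0 + 1e-12
        assert s == pytest.approx(structural_similarity(q, p))


class TestPatchDistance:
    def test_identical_patches_at_zero(self):
        p = patch_at(np.arange(27.0))
        assert patch_distance(p, p) == 0.0

    def test_constant_offset_patches(self):
        p = patch_at(np.zeros(27))
        q = patch_at(np.full(27, 3.0))
        assert patch_distance(p, q) == pytest.approx(9.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            patch_distance(patch_at(np.zeros(27)), patch_at(np.zeros(8)))

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = patch_at(rng.uniform(0, 300, 27))
        q = patch_at(rng.uniform(0, 300, 27))
        assert patch_distance(p, q) == pytest.approx(patch_distance(q, p))


class TestAdaptiveH:
    def test_identical_candidate_gives_epsilon(self):
        p = patch_at(np.arange(27.0))
        assert adaptive_h(p, [p], 0.1, 1e-6) == pytest.approx(1e-6)

    def test_minimum_distance_four_evaluates_directly(self):
        p = patch_at(np.zeros(27))
        q = patch_at(np.full(27, 2.0))  # d2 = 4
        assert adaptive_h(p, [q], 0.1, 1e-6) == pytest.approx(0.400001)

    def test_lambda_scales_linearly(self):
        p = patch_at(np.zeros(27))
        q = patch_at(np.full(27, 2.0))
        h1 = adaptive_h(p, [q], 1.0, 1e-6)
        h01 = adaptive_h(p, [q], 0.1, 1e-6)
        assert (h1 - 1e-6) == pytest.approx(10 * (h01 - 1e-6))

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            adaptive_h(patch_at(np.zeros(27)), [], 0.1, 1e-6)


class TestWeights:
    def test_identical_patch_zero_offset_weight_one(self):
        p = flat_patch(150.0, 20.0)
        assert bilateral_weight(p, p, h=1.0, sigma_d_mm=8.0, ss_threshold=0.97) \
            == pytest.approx(1.0)

    def test_identical_patch_8mm_offset_decays_to_inv_e(self):
        p = flat_patch(150.0, 20.0, center=(0, 0, 0))
        q = flat_patch(150.0, 20.0, center=(8, 0, 0))
        w = bilateral_weight(p, q, h=1.0, sigma_d_mm=8.0, ss_threshold=0.97)
        assert w == pytest.approx(math.exp(-1.0))

    def test_preselection_gate_zeroes_weight(self):
        p = flat_patch(100.0, 10.0)
        q = flat_patch(200.0, 10.0)  # ss = 0.8 < 0.97
        assert bilateral_weight(p, q, 1.0, 8.0, 0.97) == 0.0
        assert classical_weight(p, q, 1.0, 0.97) == 0.0

    def test_classical_unit_exponent(self):
        p = patch_at(np.zeros(27))
        p2 = flat_patch(150.0, 20.0)
        assert classical_weight(p2, p2, h=2.0, ss_threshold=0.97) == 1.0
        # d2 = h^2 -> e^-1: candidate at constant offset h from the target
        h = 2.0
        vals = p2.values + h
        q = Patch.from_values(vals, (0, 0, 0))
        assert classical_weight(p2, q, h=h, ss_threshold=0.0) \
            == pytest.approx(math.exp(-1.0))

    @given(st.integers(1, 30))
    def test_weight_strictly_decreases_with_center_offset(self, off):
        p = flat_patch(150.0, 20.0, center=(0, 0, 0))
        q_near = flat_patch(150.0, 20.0, center=(off, 0, 0))
        q_far = flat_patch(150.0, 20.0, center=(off + 1, 0, 0))
        w_near = bilateral_weight(p, q_near, 1.0, 8.0, 0.5)
        w_far = bilateral_weight(p, q_far, 1.0, 8.0, 0.5)
        assert w_far < w_near

    @given(st.integers(0, 2**31 - 1))
    def test_raising_gate_never_increases_weight(self, seed):
        rng = np.random.default_rng(seed)
        p = patch_at(rng.uniform(50, 250, 27))
        q = patch_at(rng.uniform(50, 250, 27))
        lo = bilateral_weight(p, q, 1.0, 8.0, ss_threshold=0.5)
        hi = bilateral_weight(p, q, 1.0, 8.0, ss_threshold=0.99)
        assert hi <= lo


class TestBlockCenterGrid:
    def test_spacing_one_enumerates_all_voxels(self):
        centers = block_center_grid((6, 6, 6), block_spacing=1, block_radius=0)
        assert len(centers) == 216

    def test_spacing_two_even_axis_gives_exact_eighth(self):
        full = block_center_grid((32, 32, 32), 1, 1)
        half = block_center_grid((32, 32, 32), 2, 1)
        assert len(full) == 8 * len(half)

    def test_tail_center_appended_when_uncovered(self):
        # L=10, spacing 3, radius 1: centers 0,3,6,9? last regular 9 covers;
        # with L=11: 0,3,6,9 covers to 10 -> no tail. L=12: 0,3,6,9 covers 10,
        # but 11 uncovered -> tail at 10.
        c = block_center_grid((12, 3, 3), 3, 1)
        xs = sorted(set(c[:, 0]))
        assert xs == [0, 3, 6, 9, 10]

    def test_roi_restriction_keeps_covering_centers_only(self):
        roi = np.zeros((12, 12, 12), np.uint8)
        roi[5, 5, 5] = 1
        centers = block_center_grid((12, 12, 12), 2, 1, roi)
        # blocks of radius 1 centered at 4/5/6 per axis touch the voxel,
        # but only even positions (plus no tail here) are centers
        assert {tuple(c) for c in centers} == {
            (x, y, z) for x in (4, 6) for y in (4, 6) for z in (4, 6)
        }


class TestFusionOperations:
    def test_matches_brute_force_oracle(self, random_fusion_instance):
        subject, library, roi, img, tmpls, labs = random_fusion_instance
        cfg = ic.FusionConfig(n_templates=3, pyramid_scales=[1],
                              patch_radius=[1], search_radius=[1],
                              ss_threshold=0.9)
        got = voxelwise_fusion(subject, library, roi, cfg, level=0)
        votes, mass, proc, fb = naive_voxelwise_fusion(
            img, tmpls, labs, roi.data, 1, 1, cfg.lambda_h, cfg.epsilon_h,
            cfg.sigma_d_mm, 0.9)
        assert np.abs(got.votes - votes).max() < 1e-10
        assert np.abs(got.weight_mass - mass).max() < 1e-10
        assert np.array_equal(got.processed, proc)
        assert np.array_equal(got.fallback, fb)

    def test_degenerate_blockwise_equals_voxelwise_bitwise(
            self, random_fusion_instance):
        subject, library, roi, *_ = random_fusion_instance
        cfg = ic.FusionConfig(n_templates=3, pyramid_scales=[1],
                              patch_radius=[1], search_radius=[2],
                              block_radius=0, block_spacing=1,
                              ss_threshold=0.9)
        a = voxelwise_fusion(subject, library, roi, cfg, level=0)
        b = blockwise_fusion(subject, library, roi, cfg, level=0)
        assert np.array_equal(a.votes, b.votes)
        assert np.array_equal(a.weight_mass, b.weight_mass)
        assert np.array_equal(a.processed, b.processed)

    @pytest.mark.parametrize("label", [0, 1])
    def test_unanimous_labels_give_unanimous_votes(self, label,
                                                   random_fusion_instance):
        subject, library, roi, img, tmpls, _ = random_fusion_instance
        lib = ic.TemplateLibrary([
            (v, ic.BinaryMask(np.full(v.shape, label, np.uint8)))
            for v, _ in library
        ])
        cfg = ic.FusionConfig(n_templates=3, pyramid_scales=[1],
                              patch_radius=[1], search_radius=[1],
                              ss_threshold=0.0)
        out = blockwise_fusion(subject, lib, roi, cfg, level=0)
        sel = out.processed > 0
        assert np.all(out.votes[sel] == float(label))

    def test_votes_are_convex_combinations(self, random_fusion_instance):
        subject, library, roi, *_ = random_fusion_instance
        cfg = ic.FusionConfig(n_templates=3, pyramid_scales=[1],
                              patch_radius=[1], search_radius=[2],
                              ss_threshold=0.9)
        out = blockwise_fusion(subject, library, roi, cfg, level=0)
        sel = out.processed > 0
        assert np.all(out.votes[sel] >= 0.0)
        assert np.all(out.votes[sel] <= 1.0)
        assert np.all(out.weight_mass >= 0.0)

    def test_template_order_does_not_change_votes(self, random_fusion_instance):
        subject, library, roi, *_ = random_fusion_instance
        cfg = ic.FusionConfig(n_templates=3, pyramid_scales=[1],
                              patch_radius=[1], search_radius=[1],
                              ss_threshold=0.9)
        a = blockwise_fusion(subject, library, roi, cfg, level=0)
        b = blockwise_fusion(subject, library.subset([2, 0, 1]), roi, cfg,
                             level=0)
        assert np.allclose(a.votes, b.votes, atol=1e-12)

    def test_empty_roi_rejected(self, random_fusion_instance):
        subject, library, _, *_ = random_fusion_instance
        empty = ic.BinaryMask(np.zeros(subject.shape, np.uint8))
        cfg = ic.FusionConfig(n_templates=3)
        with pytest.raises(ValueError, match="ROI"):
            voxelwise_fusion(subject, library, empty, cfg)

    def test_self_matching_template_reproduces_its_labels(self):
        # single template identical to the subject: zero-distance self-match
        # dominates, so votes reproduce the template labels on a phantom
        # whose search neighbourhoods are label-coherent
        spec_kw = dict(shape=(16, 16, 16), skull_axes=(6.0, 5.5, 5.0),
                       ic_axes=(5.0, 4.5, 4.0), gm_axes=(4.0, 3.5, 3.0),
                       wm_axes=(2.5, 2.0, 1.8), ventricle_axes=(0.8, 0.6, 0.5),
                       noise_sd=0.0, deformation_amplitude=0.0)
        vol, msk, _ = ic.make_phantom(ic.PhantomSpec(**spec_kw))
        lib = ic.TemplateLibrary([(vol, msk)])
        roi = ic.BinaryMask(np.ones(vol.shape, np.uint8))
        cfg = ic.FusionConfig(n_templates=1, pyramid_scales=[1],
                              patch_radius=[1], search_radius=[1])
        out = voxelwise_fusion(vol, lib, roi, cfg, level=0)
        got = threshold_votes(out)
        assert np.array_equal(got.data, msk.data)


class TestThresholdVotes:
    def test_threshold_is_inclusive_at_half(self):
        votes = ic.VoteVolume(np.full((2, 2, 2), 0.5), np.ones((2, 2, 2)),
                              np.ones((2, 2, 2), np.uint8),
                              np.zeros((2, 2, 2), np.uint8))
        assert threshold_votes(votes).data.sum() == 8

    def test_just_below_half_maps_to_zero(self):
        votes = ic.VoteVolume(np.full((2, 2, 2), 0.4999), np.ones((2, 2, 2)),
                              np.ones((2, 2, 2), np.uint8),
                              np.zeros((2, 2, 2), np.uint8))
        assert threshold_votes(votes).data.sum() == 0

    def test_unprocessed_voxels_stay_zero(self):
        proc = np.zeros((2, 2, 2), np.uint8)
        proc[0, 0, 0] = 1
        votes = ic.VoteVolume(np.ones((2, 2, 2)), proc.astype(float), proc,
                              np.zeros((2, 2, 2), np.uint8))
        assert threshold_votes(votes).data.sum() == 1


def test_extract_patch_clips_at_border():
    vol = ic.IntensityVolume(np.arange(64.0).reshape(4, 4, 4))
    p = extract_patch(vol, (0, 0, 0), radius=1)
    assert p.values.size == 8  # 2x2x2 corner patch
    assert p.center_index == (0, 0, 0)
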