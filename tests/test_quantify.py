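"""Skeleton morphometry and gliding-box lacunarity.

The lacunarity oracle is a literal double loop over window positions,
implemented here independently of the summed-area-table production code.
"""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from glutenpna import default_spec, generate_network_image
from glutenpna.quantify import (AttributeProfile, EmptyMaskError,
                                compute_profile, gliding_box_lacunarity,
                                mean_protein_width, path_lengths,
                                skeletonize_mask)
from glutenpna.segment import BinaryMask, segment_protein


def brute_force_lacunarity(mask: np.ndarray, box_sizes):
    """Oracle: Λ(r) = var/mean² of box masses by explicit window loops."""
    per_size = {}
    h, w = mask.shape
    for r in box_sizes:
        masses = np.empty((h - r + 1, w - r + 1), dtype=np.int64)
        for i in range(h - r + 1):
            for j in range(w - r + 1):
                masses[i, j] = mask[i:i + r, j:j + r].sum()
        per_size[r] = float(np.var(masses) / np.mean(masses) ** 2)
    return per_size, float(np.mean(list(per_size.values())))


def plus_sign(arm=21, width=3, size=64):
    mask = np.zeros((size, size), dtype=bool)
    c = size // 2
    half = width // 2
    mask[c - half:c + half + 1, c - arm:c + arm + 1] = True
    mask[c - arm:c + arm + 1, c - half:c + half + 1] = True
    return mask


def ribbon(length=40, width=3, size=64, horizontal=True):
    mask = np.zeros((size, size), dtype=bool)
    c = size // 2
    half = width // 2
    if horizontal:
        mask[c - half:c + half + 1, 10:10 + length] = True
    else:
        mask[10:10 + length, c - half:c + half + 1] = True
    return mask


class TestSkeletonTopology:
    def test_plus_sign_one_junction_four_endpoints(self):
        graph = skeletonize_mask(BinaryMask(plus_sign(), 1.0))
        assert graph.n_junctions == 1
        assert graph.n_endpoints == 4

    def test_straight_ribbon_no_junction_two_endpoints(self):
        graph = skeletonize_mask(BinaryMask(ribbon(), 1.0))
        assert graph.n_junctions == 0
        assert graph.n_endpoints == 2

    def test_empty_mask_empty_graph(self):
        graph = skeletonize_mask(BinaryMask(np.zeros((32, 32), bool), 1.0))
        assert graph.n_junctions == graph.n_endpoints == graph.n_components == 0

    def test_junctions_lie_on_skeleton(self):
        micro, _ = generate_network_image(
            replace(default_spec("branched", seed=2), size_px=256,
                    n_seeds=240, starch_disc_count=3))
        graph = skeletonize_mask(segment_protein(micro))
        for r, c in np.round(graph.junctions).astype(int):
            assert graph.skeleton[r, c]

    def test_endpoints_have_one_neighbor(self):
        graph = skeletonize_mask(BinaryMask(plus_sign(), 1.0))
        skel = graph.skeleton.astype(int)
        for r, c in graph.endpoints:
            assert skel[r - 1:r + 2, c - 1:c + 2].sum() == 2

    @pytest.mark.parametrize("transform", [
        lambda m: np.rot90(m).copy(),
        lambda m: np.rot90(m, 2).copy(),
        lambda m: np.fliplr(m).copy(),
    ], ids=["rot90", "rot180", "mirror"])
    def test_counts_invariant_under_symmetry_on_fixtures(self, transform):
        for mask in (plus_sign(), ribbon(), ribbon(horizontal=False)):
            base = skeletonize_mask(BinaryMask(mask, 1.0))
            moved = skeletonize_mask(BinaryMask(transform(mask), 1.0))
            assert moved.n_junctions == base.n_junctions
            assert moved.n_endpoints == base.n_endpoints

    def test_counts_near_invariant_on_dense_synthetic(self):
        """Thinning is not exactly equivariant on dense masks; counts
        must still agree to within 15% under rotation."""
        micro, _ = generate_network_image(
            replace(default_spec("branched", seed=3), size_px=256,
                    n_seeds=240, starch_disc_count=3))
        mask = segment_protein(micro).mask
        base = skeletonize_mask(BinaryMask(mask, 1.0))
        rot = skeletonize_mask(BinaryMask(np.rot90(mask).copy(), 1.0))
        assert rot.n_junctions == pytest.approx(base.n_junctions, rel=0.15)
        assert rot.n_endpoints == pytest.approx(base.n_endpoints, rel=0.15)


class TestPathLengths:
    def test_horizontal_eleven_pixels_is_ten_um(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[16, 10:21] = True
        graph = skeletonize_mask(BinaryMask(mask, 1.0))
        (_, length), = path_lengths(graph)
        assert length == pytest.approx(10.0)

    def test_diagonal_eleven_pixels_is_ten_root_two(self):
        mask = np.zeros((32, 32), dtype=bool)
        idx = np.arange(11)
        mask[10 + idx, 10 + idx] = True
        graph = skeletonize_mask(BinaryMask(mask, 1.0))
        (_, length), = path_lengths(graph)
        assert length == pytest.approx(10 * np.sqrt(2))

    def test_single_pixel_component_counts_one_pixel_size(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 5] = True
        graph = skeletonize_mask(BinaryMask(mask, 0.5))
        assert graph.segment_lengths_um.tolist() == [0.5]

    def test_total_length_matches_ground_truth_on_sparse_noiseless(self):
        spec = replace(default_spec("branched", seed=0), noise_sd=0.0,
                       n_seeds=60, fragmentation_rate=0.0, starch_disc_count=0)
        micro, gt = generate_network_image(spec)
        graph = skeletonize_mask(segment_protein(micro))
        assert graph.total_length_um == pytest.approx(
            gt.total_drawn_length_um, rel=0.05)


class TestProteinWidth:
    def test_solid_ribbon_width(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 50:55] = True          # 100 x 5 ribbon
        bm = BinaryMask(mask, 1.0)
        width = mean_protein_width(bm, skeletonize_mask(bm))
        assert width == pytest.approx(5.0, rel=0.15)

    def test_width_scales_with_ribbon_thickness(self):
        def width_of(w):
            mask = np.zeros((120, 120), dtype=bool)
            mask[10:110, 60 - w // 2:60 + w // 2 + 1] = True
            bm = BinaryMask(mask, 1.0)
            return mean_protein_width(bm, skeletonize_mask(bm))
        ratio = width_of(9) / width_of(5)
        assert 1.7 < ratio < 2.0

    def test_empty_skeleton_raises(self):
        bm = BinaryMask(np.zeros((32, 32), bool), 1.0)
        with pytest.raises(EmptyMaskError):
            mean_protein_width(bm, skeletonize_mask(bm))


class TestLacunarity:
    def test_all_foreground_is_zero(self):
        bm = BinaryMask(np.ones((64, 64), bool), 1.0)
        per_size, summary = gliding_box_lacunarity(bm, (2, 4, 8))
        assert summary == 0.0
        assert all(v == 0.0 for v in per_size.values())

    def test_matches_brute_force_oracle_bitwise(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mask = rng.random((64, 64)) < rng.uniform(0.2, 0.6)
            if not mask.any():
                continue
            got_sizes, got_summary = gliding_box_lacunarity(
                BinaryMask(mask, 1.0), (2, 4, 8))
            exp_sizes, exp_summary = brute_force_lacunarity(mask, (2, 4, 8))
            assert got_sizes == exp_sizes
            assert got_summary == exp_summary

    def test_clustered_exceeds_uniform_at_same_density(self):
        """Clustered blobs have larger gaps, hence larger lacunarity,
        than the same number of foreground pixels spread uniformly."""
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            clustered = np.zeros((64, 64), dtype=bool)
            for _ in range(4):
                r, c = rng.integers(8, 56, size=2)
                clustered[r - 4:r + 4, c - 4:c + 4] = True
            n = clustered.sum()
            flat = np.zeros(64 * 64, dtype=bool)
            flat[rng.choice(64 * 64, size=n, replace=False)] = True
            uniform = flat.reshape(64, 64)
            _, lac_clustered = gliding_box_lacunarity(
                BinaryMask(clustered, 1.0), (2, 4, 8, 16))
            _, lac_uniform = gliding_box_lacunarity(
                BinaryMask(uniform, 1.0), (2, 4, 8, 16))
            assert lac_clustered > lac_uniform

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            gliding_box_lacunarity(BinaryMask(np.zeros((64, 64), bool), 1.0))

    def test_box_size_bounds_enforced(self):
        bm = BinaryMask(np.ones((64, 64), bool), 1.0)
        with pytest.raises(ValueError):
            gliding_box_lacunarity(bm, (1,))
        with pytest.raises(ValueError):
            gliding_box_lacunarity(bm, (48,))


class TestComputeProfile:
    def test_plus_sign_branching_rate(self):
        mask = plus_sign()
        profile = compute_profile(BinaryMask(mask, 1.0), (2, 4, 8))
        assert profile.protein_area_um2 == mask.sum()
        assert profile.branching_rate == pytest.approx(1000.0 / mask.sum())
        assert profile.endpoint_rate == pytest.approx(4000.0 / mask.sum())
        assert profile.n_components == 1

    def test_two_disjoint_ribbons(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:13, 5:45] = True
        mask[40:43, 5:45] = True
        profile = compute_profile(BinaryMask(mask, 1.0), (2, 4, 8))
        assert profile.n_components == 2
        graph = skeletonize_mask(BinaryMask(mask, 1.0))
        assert graph.n_endpoints == 4

    def test_generated_image_all_attributes_finite_positive(self, config):
        micro, _ = generate_network_image(
            replace(default_spec("branched", seed=4), size_px=256,
                    n_seeds=240, starch_disc_count=3))
        profile = compute_profile(segment_protein(micro),
                                  tuple(config.box_sizes_px))
        for field in ("lacunarity", "branching_rate", "endpoint_rate",
                      "avg_protein_length_um", "protein_width_um",
                      "protein_area_um2"):
            value = getattr(profile, field)
            assert np.isfinite(value) and value > 0

    def test_empty_mask_error_lists_attributes(self):
        with pytest.raises(EmptyMaskError, match="lacunarity.*branching"):
            compute_profile(BinaryMask(np.zeros((64, 64), bool), 1.0))

    def test_scale_consistency(self):
        """Doubling the pixel size doubles lengths and widths, quadruples
        areas, and leaves lacunarity and rates-per-area consistent."""
        mask = plus_sign()
        p1 = compute_profile(BinaryMask(mask, 1.0), (2, 4, 8))
        p2 = compute_profile(BinaryMask(mask, 2.0), (2, 4, 8))
        assert p2.avg_protein_length_um == pytest.approx(2 * p1.avg_protein_length_um)
        assert p2.protein_width_um == pytest.approx(2 * p1.protein_width_um)
        assert p2.protein_area_um2 == pytest.approx(4 * p1.protein_area_um2)
        assert p2.lacunarity == pytest.approx(p1.lacunarity)
        assert p2.branching_rate == pytest.approx(p1.branching_rate / 4)


class TestSkeletonSurgeryMonotonicity:
    def test_cutting_interior_segments_opens_ends_and_shortens(self):
        """Deleting interior skeleton segments never decreases the
        endpoint count and never increases the mean component length —
        the thread-rupture mechanism at mask level."""
        for seed in range(20):
            spec = replace(default_spec("branched", seed=seed), size_px=256,
                           n_seeds=240, starch_disc_count=0, noise_sd=0.0,
                           fragmentation_rate=0.0)
            micro, _ = generate_network_image(spec)
            mask = segment_protein(micro)
            graph = skeletonize_mask(mask)
            skel = graph.skeleton
            neighbors = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                                         mode="constant") - skel.astype(int)
            # interior path pixels well away from junctions and endpoints
            special = skel & (neighbors != 2)
            far = ndimage.distance_transform_edt(~special) > 4
            candidates = np.argwhere(skel & (neighbors == 2) & far)
            rng = np.random.default_rng(seed)
            rng.shuffle(candidates)
            picked: list[np.ndarray] = []
            for p in candidates:
                if all(np.abs(p - q).max() >= 6 for q in picked):
                    picked.append(p)
                if len(picked) == 15:
                    break
            prev_e = graph.n_endpoints
            prev_len = np.mean(graph.segment_lengths_um)
            cut = skel.copy()
            for k, (r, c) in enumerate(picked, start=1):
                cut[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = False
                if k in (5, 15):
                    g = skeletonize_mask(BinaryMask(cut.copy(), mask.pixel_size_um))
                    assert g.n_endpoints >= prev_e
                    assert np.mean(g.segment_lengths_um) <= prev_len + 1e-9
                    prev_e = g.n_endpoints
                    prev_len = np.mean(g.segment_lengths_um)
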