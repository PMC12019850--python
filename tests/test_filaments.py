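"""Filament enhancement, segmentation, fragment pool, and grouping."""

import numpy as np
import pytest

from axonmt.filaments import (
    Filament,
    GroupingConfig,
    enhance_lft_oft,
    extract_filaments,
    filter_filaments,
    fragment_pool,
    group_fragments,
    segment_otsu,
)


def brute_force_otsu(image, nbins=256):
    """Exhaustive inter-class-variance maximization over histogram bins."""
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[k - 1 : k + 1].mean()
    return best_thr


class TestEnhance:
    def test_uniform_image_constant_response(self):
        enhanced = enhance_lft_oft(np.full((41, 41), 3.0), radius_px=10)
        np.testing.assert_allclose(enhanced.lft, 3.0, atol=1e-12)

    def test_horizontal_line_response_and_orientation(self):
        image = np.zeros((41, 41))
        image[20, :] = 1.0
        enhanced = enhance_lft_oft(image, radius_px=10, n_rotations=40)
        assert enhanced.lft[20, 20] == pytest.approx(1.0)
        assert enhanced.oft[20, 20] == pytest.approx(0.0, abs=np.pi / 40)

    def test_line_outscores_isolated_pixel_of_equal_peak(self):
        image = np.zeros((41, 41))
        image[10, 10] = 1.0  # isolated bright pixel
        image[30, 10:31] = 1.0  # 21-px line, same peak value
        enhanced = enhance_lft_oft(image, radius_px=10)
        assert enhanced.lft[30, 20] > enhanced.lft[10, 10]

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            enhance_lft_oft(np.zeros((15, 15)), radius_px=10)


class TestSegmentOtsu:
    def test_half_zeros_half_ones(self):
        image = np.zeros((10, 10))
        image[:, 5:] = 1.0
        mask = segment_otsu(image)
        np.testing.assert_array_equal(mask, image == 1.0)

    def test_matches_brute_force_on_bimodal_mixture(self):
        rng = np.random.default_rng(3)
        image = np.concatenate([rng.normal(2, 0.5, 3000), rng.normal(8, 1.0, 2000)]).reshape(50, 100)
        from skimage.filters import threshold_otsu

        fast = threshold_otsu(image, nbins=256)
        brute = brute_force_otsu(image)
        # same histogram bin: both separate the two modes identically
        assert fast == pytest.approx(brute, abs=(image.max() - image.min()) / 256)
        np.testing.assert_array_equal(segment_otsu(image), image > fast)

    def test_constant_image_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_otsu(np.full((8, 8), 5.0))
        assert not mask.any()


class TestFragmentPool:
    def test_crossing_lines_split_into_four_fragments(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[20, 10:31] = True
        mask[10:31, 20] = True
        pool = fragment_pool(mask)
        assert len(pool) == 4

    def test_straight_line_is_single_fragment_with_opposite_tips(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[20, 5:36] = True
        pool = fragment_pool(mask)
        assert len(pool) == 1
        tips = pool[0].tip_directions
        # outward directions at the two ends are antiparallel along the line
        assert np.dot(tips[0], tips[1]) == pytest.approx(-1.0, abs=0.05)

    def test_empty_mask_gives_empty_pool(self):
        assert fragment_pool(np.zeros((10, 10), dtype=bool)) == []

    def test_chains_are_ordered_and_junction_free(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((60, 60), dtype=bool)
        rr = np.arange(5, 55)
        cc = np.clip(30 + np.cumsum(rng.integers(-1, 2, rr.size)), 1, 58)
        mask[rr, cc] = True
        for fragment in fragment_pool(mask):
            steps = np.abs(np.diff(fragment.pixels, axis=0))
            assert steps.max() <= 1  # 8-connected chain
            assert len(np.unique(fragment.pixels, axis=0)) == len(fragment.pixels)


class TestGrouping:
    def line_fragment_pool(self, *segments):
        mask = np.zeros((80, 120), dtype=bool)
        for row, c0, c1 in segments:
            mask[row, c0:c1] = True
        return fragment_pool(mask)

    def test_collinear_fragments_joined_across_gap(self):
        pool = self.line_fragment_pool((40, 10, 30), (40, 35, 55))
        result = group_fragments(pool)
        assert len(result.filaments) == 1
        assert result.filaments[0].composite
        assert len(result.joins) == 1

    def test_perpendicular_fragments_never_joined(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[40, 10:30] = True  # horizontal
        mask[45:65, 35] = True  # vertical, tips ~7 px apart
        result = group_fragments(fragment_pool(mask))
        assert len(result.filaments) == 2
        assert not result.joins

    def test_short_composite_excluded_from_statistics(self):
        # 10 px total = 260 nm < 390 nm minimum
        pool = self.line_fragment_pool((40, 10, 15), (40, 18, 23))
        result = group_fragments(pool)
        assert len(result.filaments) == 1
        assert filter_filaments(result.filaments) == []

    def test_every_accepted_join_satisfies_hard_constraints(self):
        from axonmt import smlm, synth

        cfg = GroupingConfig()
        truth, _, locs = synth.gen_microtubule_array(synth.ArrayModel.pc12(), seed=4)
        volume = smlm.render_volume(locs)
        z_mid = volume.origin_nm[2] + volume.intensity.shape[2] * volume.voxel_size_nm[2] / 2
        section = smlm.select_section(volume, z_mid, 150.0)
        result = extract_filaments(section, cfg)
        assert result.joins  # the scenario produces joins
        for join in result.joins:
            assert join.gap_px <= cfg.search_radius_px
            assert join.gap_vector_angle_deg <= cfg.max_gap_vector_angle_deg
            assert join.tip_angle_diff_deg <= cfg.max_angle_diff_deg
            assert join.endpoint_orientation_diff_deg <= cfg.max_endpoint_orientation_diff_deg
            assert join.curvature_rad_per_um <= cfg.max_curvature_rad_per_um

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GroupingConfig(search_angle_deg=0.0)
        with pytest.raises(ValueError):
            GroupingConfig(min_filament_length_px=-1)


class TestFilamentGeometry:
    def test_straight_filament_straightness_is_one(self):
        filament = Filament(points_nm=np.stack([np.arange(50) * 100.0, np.zeros(50)], axis=1))
        assert filament.straightness == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_straightness(self):
        theta = np.linspace(0, np.pi, 500)
        points = 1000.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        filament = Filament(points_nm=points)
        # diameter / half-circumference = 2 / pi
        assert filament.straightness == pytest.approx(2 / np.pi, rel=0.01)

    def test_straightness_bounded_for_random_paths(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            points = np.cumsum(rng.normal(0, 50, (30, 2)), axis=0)
            filament = Filament(points_nm=points)
            assert 0 < filament.straightness <= 1.0
            assert filament.contour_length_um >= filament.end_to_end_um


class TestRecovery:
    def test_sparse_array_mean_length_and_mass_recovered(self):
        from axonmt import smlm, synth

        model = synth.ArrayModel.recovery_benchmark()
        true_lengths, recovered = [], []
        for seed in (0, 1, 2, 3):
            truth, _, locs = synth.gen_microtubule_array(model, seed=seed)
            volume = smlm.render_volume(locs)
            z_mid = volume.origin_nm[2] + volume.intensity.shape[2] * volume.voxel_size_nm[2] / 2
            section = smlm.select_section(volume, z_mid, 150.0)
            result = extract_filaments(section)
            true_lengths.extend(truth["length_um"])
            recovered.extend(f.contour_length_um for f in result.filaments)
            # ground-truth chains are nearly straight; recovered ones must be too
            assert all(f.straightness >= 0.95 for f in result.filaments)
        assert np.mean(recovered) == pytest.approx(np.mean(true_lengths), rel=0.15)
        assert np.sum(recovered) == pytest.approx(np.sum(true_lengths), rel=0.15)

    def test_clutter_degrades_gracefully(self):
        # more clutter must not increase retained spurious filaments in most seeds
        import dataclasses

        from axonmt import smlm, synth

        base = synth.ArrayModel.recovery_benchmark()
        noisy = dataclasses.replace(base, clutter_per_um3=20 * base.clutter_per_um3)
        worse = 0
        seeds = range(6)
        for seed in seeds:
            counts = []
            for model in (base, noisy):
                truth, _, locs = synth.gen_microtubule_array(model, seed=seed)
                volume = smlm.render_volume(locs)
                z_mid = volume.origin_nm[2] + volume.intensity.shape[2] * volume.voxel_size_nm[2] / 2
                section = smlm.select_section(volume, z_mid, 150.0)
                counts.append(len(extract_filaments(section).filaments))
            worse += counts[1] > counts[0] + len(truth) // 2
        assert worse <= len(list(seeds)) / 2
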