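"""Radiomic feature extractor: analytic limits and brute-force oracles."""

import numpy as np
import pytest

import nodulex as nx
from nodulex import qif
from oracles import (
    box_count_oracle,
    lacunarity_oracle,
    moments_oracle,
    ngtdm_oracle,
)


def disk_mask(r, pad=3):
    n = 2 * r + 2 * pad + 1
    gx, gy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2
    return (gx - c) ** 2 + (gy - c) ** 2 <= r * r


class TestAutoSegment:
    def test_recovers_bright_sphere(self, sphere_phantom):
        spec, volume, mask = sphere_phantom
        auto = nx.auto_segment(volume, spec.nodules[0].center)
        recovered = (auto & mask).sum() / mask.sum()
        assert recovered >= 0.9

    def test_background_seed_falls_back_to_sphere(self):
        rng = np.random.default_rng(0)
        volume = nx.CTVolume(
            hu=rng.normal(-700, 30, (32, 32, 32)), spacing=(1, 1, 1),
            patient_id="P",
        )
        auto = nx.auto_segment(volume, (16, 16, 16))
        # lattice points within radius 3 of the seed
        gx, gy, gz = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        expected = (gx - 16) ** 2 + (gy - 16) ** 2 + (gz - 16) ** 2 <= 9
        np.testing.assert_array_equal(auto, expected)

    def test_output_connected_and_contains_seed(self, sphere_phantom):
        from scipy import ndimage

        spec, volume, _ = sphere_phantom
        auto = nx.auto_segment(volume, spec.nodules[0].center)
        labels, n = ndimage.label(auto)
        assert n == 1
        seed = tuple(int(round(c)) for c in spec.nodules[0].center)
        assert auto[seed]

    def test_seed_outside_volume_rejected(self, sphere_phantom):
        _, volume, _ = sphere_phantom
        with pytest.raises(ValueError, match="outside"):
            nx.auto_segment(volume, (200, 10, 10))


class TestMaxAreaSlice:
    def test_sphere_central_slice(self, sphere_phantom):
        spec, volume, mask = sphere_phantom
        nod = qif.SegmentedNodule(volume.hu, mask, volume.spacing)
        assert qif.max_area_slice(nod) == 12

    def test_single_slice_mask(self):
        mask = np.zeros((8, 8, 5), bool)
        mask[2:5, 2:5, 3] = True
        nod = qif.SegmentedNodule(np.zeros((8, 8, 5)), mask)
        assert qif.max_area_slice(nod) == 3

    def test_tie_takes_smaller_index(self):
        mask = np.zeros((8, 8, 5), bool)
        mask[2:5, 2:5, 1] = True
        mask[2:5, 2:5, 4] = True
        nod = qif.SegmentedNodule(np.zeros((8, 8, 5)), mask)
        assert qif.max_area_slice(nod) == 1


class TestGeometry:
    @pytest.mark.parametrize("r", [5, 10])
    def test_disk_circularity_near_one(self, r):
        g = qif.geometry_features(disk_mask(r))
        assert 0.9 <= g["circularity"] <= 1.1

    def test_square_moment_ratio_one(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        g = qif.geometry_features(mask)
        assert g["moment_ratio"] == pytest.approx(1.0)

    def test_bar_spans(self):
        mask = np.zeros((12, 12), bool)
        mask[2:10, 5] = True  # 8 px along x, 1 px along y
        g = qif.geometry_features(mask, spacing2=(0.7, 0.7))
        assert g["span_x"] == pytest.approx(8 * 0.7)
        assert g["span_y"] == pytest.approx(0.7)

    def test_single_pixel_defined(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        g = qif.geometry_features(mask)
        assert g["moment_ratio"] == 1.0
        assert g["perimeter"] > 0
        assert g["n_pixels"] == 1

    def test_area_scales_with_spacing(self):
        mask = disk_mask(5)
        g1 = qif.geometry_features(mask, (1.0, 1.0))
        g2 = qif.geometry_features(mask, (2.0, 2.0))
        assert g2["area"] == pytest.approx(4 * g1["area"])


class TestHuStatistics:
    def test_constant_region(self):
        s = qif.hu_statistics([7.0] * 20)
        assert s["hu_sd"] == 0 and s["hu_entropy"] == 0
        assert s["hu_skewness"] == 0 and s["hu_kurtosis"] == 0

    def test_hand_arithmetic_example(self):
        s = qif.hu_statistics([0, 0, 0, 1])
        assert s["hu_mean"] == pytest.approx(0.25)
        assert s["hu_variance"] == pytest.approx(0.1875)

    def test_two_valued_entropy_one_bit(self):
        s = qif.hu_statistics([0] * 8 + [10] * 8)
        assert s["hu_entropy"] == pytest.approx(1.0)

    def test_moments_match_direct_formulas(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            values = rng.normal(size=rng.integers(3, 40)) * 100
            s = qif.hu_statistics(values)
            mean, sd, var, skew, kurt = moments_oracle(values)
            assert s["hu_mean"] == pytest.approx(mean, rel=1e-9)
            assert s["hu_sd"] == pytest.approx(sd, rel=1e-9)
            assert s["hu_variance"] == pytest.approx(var, rel=1e-9)
            assert s["hu_skewness"] == pytest.approx(skew, rel=1e-9, abs=1e-9)
            assert s["hu_kurtosis"] == pytest.approx(kurt, rel=1e-9)


class TestDifferenceImage:
    def test_constant_region_all_zero(self):
        mask = disk_mask(4)
        s = qif.difference_image_statistics(np.full(mask.shape, 50.0), mask)
        assert all(v == 0 for v in s.values())

    def test_ramp_gives_constant_difference(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        hu = np.arange(10)[:, None] * 3.0 * np.ones((10, 10))
        s = qif.difference_image_statistics(hu, mask)
        assert s["diff_mean"] == pytest.approx(-3.0)
        assert s["diff_sd"] == 0

    def test_variance_matches_explicit_pair_list(self):
        rng = np.random.default_rng(2)
        mask = rng.random((8, 8)) < 0.6
        hu = rng.normal(size=(8, 8)) * 40
        diffs = [
            hu[x, y] - hu[x + 1, y]
            for x in range(7)
            for y in range(8)
            if mask[x, y] and mask[x + 1, y]
        ]
        if not diffs:
            pytest.skip("degenerate draw")
        s = qif.difference_image_statistics(hu, mask)
        _, _, var, _, _ = moments_oracle(diffs)
        assert s["diff_variance"] == pytest.approx(var, rel=1e-9)

    def test_no_valid_pairs_defined_zero(self):
        mask = np.zeros((6, 6), bool)
        mask[::2, 0] = True  # no horizontal neighbours
        s = qif.difference_image_statistics(np.random.default_rng(0).random((6, 6)), mask)
        assert all(v == 0 for v in s.values())


class TestLacunarity:
    def test_full_rectangle_all_ones(self):
        lam = qif.lacunarity(np.ones((12, 7), bool))
        np.testing.assert_allclose(lam, 1.0)

    def test_checkerboard_uniform_at_s2(self):
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        lam = qif.lacunarity(mask)
        assert lam[0] == pytest.approx(1.0)  # every 2x2 window holds 2

    def test_output_length_ten(self):
        assert len(qif.lacunarity(disk_mask(4))) == 10

    def test_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        sizes = [2**i for i in range(1, 11)]
        for _ in range(20):
            mask = rng.random((9, 7)) < rng.uniform(0.2, 0.9)
            if not mask.any():
                continue
            np.testing.assert_allclose(
                qif.lacunarity(mask), lacunarity_oracle(mask, sizes),
                rtol=1e-12,
            )


class TestNgtdm:
    def test_constant_region_limits(self):
        mask = np.ones((6, 6), bool)
        t = qif.ngtdm_features(np.full((6, 6), 100.0), mask, d=1)
        assert t["contrast"] == 0
        assert t["coarseness"] == pytest.approx(1e6)
        t2 = qif.ngtdm_features(np.full((6, 6), 100.0), mask, d=2)
        assert t == t2

    def test_two_level_toy_image_matches_oracle(self):
        img = np.array(
            [[0, 0, 1, 0, 0],
             [0, 1, 1, 1, 0],
             [1, 1, 0, 1, 1],
             [0, 1, 1, 1, 0],
             [0, 0, 1, 0, 0]], dtype=float,
        )
        mask = np.ones((5, 5), bool)
        for d in (1, 2):
            got = qif.ngtdm_features(img, mask, d=d)
            want = ngtdm_oracle(img, mask, d, qif.N_GRAY_LEVELS)
            for k in got:
                assert got[k] == pytest.approx(want[k], rel=1e-9), (d, k)

    def test_random_images_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            img = rng.normal(size=(8, 8)) * 50
            mask = rng.random((8, 8)) < 0.8
            mask[3:5, 3:5] = True
            for d in (1, 2):
                got = qif.ngtdm_features(img, mask, d=d)
                want = ngtdm_oracle(img, mask, d, qif.N_GRAY_LEVELS)
                for k in got:
                    assert got[k] == pytest.approx(want[k], rel=1e-9), (d, k)

    def test_no_valid_pixel_all_zero(self):
        mask = np.zeros((6, 6), bool)
        mask[0, :] = True  # a line: no full 3x3 neighbourhood in mask
        t = qif.ngtdm_features(np.random.default_rng(0).random((6, 6)), mask, 1)
        assert all(v == 0 for v in t.values())


class TestDistanceFeatures:
    def test_single_pixel_all_zero(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        d = qif.distance_features(mask)
        assert all(v == 0 for v in d.values())

    def test_three_by_three_hand_values(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        d = qif.distance_features(mask)
        assert d["dist_summed"] == pytest.approx(1.0)
        assert d["dist_mean"] == pytest.approx(1.0 / 9.0)

    def test_normalized_mean_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mask = rng.random((10, 10)) < 0.5
            if not mask.any():
                continue
            d = qif.distance_features(mask)
            assert 0 <= d["dist_mean_norm"] <= 1


class TestFractalDimensions:
    def test_filled_square_area_dimension_two(self):
        fd_area, _ = qif.fractal_dimensions(np.ones((256, 256), bool))
        assert fd_area == pytest.approx(2.0, abs=0.2)
        oracle = box_count_oracle(np.ones((256, 256), bool))
        assert fd_area == pytest.approx(oracle, abs=1e-9)

    def test_straight_line_perimeter_dimension_one(self):
        mask = np.zeros((128, 128), bool)
        mask[5, :] = True
        _, fd_perim = qif.fractal_dimensions(mask)
        assert fd_perim == pytest.approx(1.0, abs=0.2)

    def test_stable_under_disk_refinement(self):
        fd1, _ = qif.fractal_dimensions(disk_mask(32))
        fd2, _ = qif.fractal_dimensions(disk_mask(64))
        assert abs(fd1 - fd2) < 0.1

    def test_tiny_mask_defined_as_one(self):
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        assert qif.fractal_dimensions(mask) == (1.0, 1.0)


class TestGradientMargin:
    def test_constant_image_zero(self):
        mask = disk_mask(3)
        assert qif.gradient_margin(np.full(mask.shape, 10.0), mask) == 0

    def test_step_edge_half_height(self):
        h = 100.0
        hu = np.zeros((11, 9))
        hu[6:, :] = h
        mask = np.zeros((11, 9), bool)
        mask[6, 2:7] = True  # one-row mask lying on the step
        assert qif.gradient_margin(hu, mask) == pytest.approx(h / 2)

    def test_linear_in_contrast(self):
        rng = np.random.default_rng(6)
        mask = disk_mask(3, pad=2)
        hu = rng.normal(size=mask.shape) * 30
        one = qif.gradient_margin(hu, mask)
        two = qif.gradient_margin(2 * hu, mask)
        assert two == pytest.approx(2 * one)


class TestExtractQif:
    def test_vector_length_and_names(self, sphere_phantom):
        _, volume, mask = sphere_phantom
        vec = nx.extract_qif(qif.SegmentedNodule(volume.hu, mask, volume.spacing))
        assert vec.shape == (50,)
        assert len(qif.QIF_FEATURE_NAMES) == 50

    def test_translation_invariant_except_plane_index(self):
        rng = np.random.default_rng(7)
        hu = rng.normal(-700, 60, (40, 40, 16))
        mask = np.zeros((40, 40, 16), bool)
        mask[8:16, 8:17, 4:9] = rng.random((8, 9, 5)) < 0.8
        mask[11, 12, 6] = True
        hu[mask] += 500
        v1 = nx.extract_qif(qif.SegmentedNodule(hu, mask))
        v2 = nx.extract_qif(
            qif.SegmentedNodule(
                np.roll(hu, (7, -3, 4), axis=(0, 1, 2)),
                np.roll(mask, (7, -3, 4), axis=(0, 1, 2)),
            )
        )
        names = qif.QIF_FEATURE_NAMES
        assert v1[0] + 4 == v2[0]  # plane index shifts with the roll
        np.testing.assert_allclose(v1[1:], v2[1:], rtol=1e-9)

    def test_monotone_in_radius(self):
        vecs = []
        for r in (3.0, 5.5):
            spec = nx.PhantomSpec(
                "P", nodules=(nx.NoduleTruth(center=(32, 32, 12), radius_mm=r),),
                rng_seed=1,
            )
            volume, masks = nx.generate_scan(spec)
            vecs.append(
                nx.extract_qif(qif.SegmentedNodule(volume.hu, masks[0],
                                                   volume.spacing))
            )
        names = qif.QIF_FEATURE_NAMES
        for feat in ("n_pixels", "area", "span_x", "span_y"):
            i = names.index(feat)
            assert vecs[1][i] > vecs[0][i]

    def test_fuzz_all_features_finite(self):
        """1,000 random small nodules never produce NaN/inf features."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            shape = (
                int(rng.integers(6, 20)),
                int(rng.integers(6, 20)),
                int(rng.integers(2, 6)),
            )
            hu = rng.normal(-500, 150, shape)
            mask = rng.random(shape) < rng.uniform(0.05, 0.9)
            if not mask.any():
                mask[shape[0] // 2, shape[1] // 2, shape[2] // 2] = True
            vec = nx.extract_qif(qif.SegmentedNodule(hu, mask))
            assert np.all(np.isfinite(vec))
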