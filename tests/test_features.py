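import numpy as np
import pytest
from skimage.draw import disk

from bcdnet.features import (DEFAULT_FREQUENCIES, DEFAULT_ORIENTATIONS, FeatureBank,
                             GaborParams, assemble, crack_perimeter, extract_features,
                             gabor_bank, gabor_kernel, lbp_map, lvp_maps,
                             shape_features, statistical_features)
from bcdnet.phantom import PhantomSpec, generate_dataset


class TestGabor:
    def test_origin_value_is_real_normalization(self):
        p = GaborParams(frequency=0.25, sharpness_major=1.3, sharpness_minor=0.8,
                        orientation=0.7)
        k = gabor_kernel(p, 9)
        expected = p.frequency ** 2 / (np.pi * p.sharpness_major * p.sharpness_minor)
        assert k[4, 4] == pytest.approx(expected)
        assert k[4, 4].imag == pytest.approx(0.0)

    def test_quarter_turn_is_transpose(self):
        k0 = gabor_kernel(GaborParams(0.2, orientation=0.0), 11)
        k90 = gabor_kernel(GaborParams(0.2, orientation=np.pi / 2), 11)
        np.testing.assert_allclose(k0, k90.T, atol=1e-9)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gabor_kernel(GaborParams(0.2), 8)

    def test_constant_image_response_matches_kernel_sum(self):
        # direct convolution oracle: a constant image under reflect padding
        # responds with |sum of kernel| * c everywhere
        c = 13.0
        img = np.full((5, 5), c)
        maps = gabor_bank(img, frequencies=(0.3,), orientations=(0.5,))
        p = GaborParams(0.3, orientation=0.5)
        from bcdnet.features import _kernel_size
        k = gabor_kernel(p, _kernel_size(p))
        np.testing.assert_allclose(next(iter(maps.values())),
                                   np.full((5, 5), abs(k.sum()) * c), atol=1e-9)

    def test_bank_counting_and_nonnegativity(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        maps = gabor_bank(img)
        assert len(maps) == len(DEFAULT_FREQUENCIES) * len(DEFAULT_ORIENTATIONS)
        for m in maps.values():
            assert m.shape == img.shape
            assert np.all(m >= 0)

    def test_stripes_respond_maximally_at_aligned_orientation(self):
        # vertical stripes at frequency 0.2 (period 5 px along x)
        x = np.arange(48)
        img = np.tile(128 + 100 * np.sin(2 * np.pi * 0.2 * x), (48, 1))
        maps = gabor_bank(img, frequencies=(0.2,))
        means = {k: v[8:-8, 8:-8].mean() for k, v in maps.items()}
        assert max(means, key=means.get) == "gabor_f0.2_t0"


class TestLbp:
    def test_flat_image_codes_255(self):
        codes = lbp_map(np.full((6, 6), 9.0))
        assert np.all(codes[1:-1, 1:-1] == 255)
        assert np.all(codes[0] == 0) and np.all(codes[:, 0] == 0)

    def test_worked_example_code_85(self):
        # neighbors (E, NE, N, NW, W, SW, S, SE) = (6, 4, 6, 4, 6, 4, 6, 4)
        # around center 5 -> bits 10101010 (east first, CCW) -> 85
        img = np.full((3, 3), 5.0)
        img[1, 2], img[0, 2], img[0, 1], img[0, 0] = 6, 4, 6, 4
        img[1, 0], img[2, 0], img[2, 1], img[2, 2] = 6, 4, 6, 4
        assert lbp_map(img)[1, 1] == 85

    def test_offset_invariance(self, rng):
        img = rng.uniform(0, 200, (10, 10))
        np.testing.assert_array_equal(lbp_map(img), lbp_map(img + 57.0))

    def test_code_range(self, rng):
        codes = lbp_map(rng.uniform(0, 255, (16, 16)))
        assert codes.min() >= 0 and codes.max() <= 255


class TestLvp:
    def test_constant_image_interior_255(self):
        maps = lvp_maps(np.full((7, 7), 4.0))
        assert len(maps) == 4
        for m in maps.values():
            assert np.all(m[2:-2, 2:-2] == 255)

    def test_linear_ramp_uniform_interior(self):
        img = np.tile(np.arange(8, dtype=float), (8, 1))
        maps = lvp_maps(img)
        interior = maps["lvp_0"][2:-2, 2:-2]
        assert np.unique(interior).size == 1

    def test_offset_invariance_and_range(self, rng):
        img = rng.uniform(0, 255, (12, 12))
        m1, m2 = lvp_maps(img), lvp_maps(img + 31.0)
        for k in m1:
            np.testing.assert_array_equal(m1[k], m2[k])
            assert m1[k].min() >= 0 and m1[k].max() <= 255


class TestShape:
    def test_square_golden_values(self):
        mask = np.zeros((14, 14))
        mask[2:12, 2:12] = 1  # 10x10 filled square
        h = shape_features(mask)
        assert h[0] == pytest.approx(0.4)   # crack perimeter 40 / area 100
        assert h[1] == pytest.approx(1.0)   # moment ellipse of a square is a circle
        assert h[2] == pytest.approx(100.0)
        assert h[3] == pytest.approx(1.0)

    def test_disk_near_isotropic_and_solid(self):
        mask = np.zeros((42, 42))
        rr, cc = disk((20.5, 20.5), 15.5)  # half-pixel center: symmetric digitization
        mask[rr, cc] = 1
        h = shape_features(mask)
        assert 0.98 <= h[1] <= 1.02
        assert h[3] >= 0.98

    def test_rectangle_axis_ratio(self):
        mask = np.zeros((30, 30))
        mask[5:10, 5:25] = 1  # 20 x 5
        h = shape_features(mask)
        assert h[1] == pytest.approx(4.0, rel=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no region"):
            shape_features(np.zeros((5, 5)))

    def test_largest_component_used(self):
        mask = np.zeros((20, 20))
        mask[2:12, 2:12] = 1
        mask[15, 15] = 1  # stray pixel
        h = shape_features(mask)
        assert h[0] == pytest.approx(0.4)

    def test_compactness_halves_when_size_doubles(self):
        small = np.zeros((30, 30)); small[5:15, 5:15] = 1
        big = np.zeros((50, 50)); big[5:25, 5:25] = 1
        assert shape_features(big)[0] == pytest.approx(shape_features(small)[0] / 2)

    def test_crack_perimeter_square(self):
        mask = np.zeros((6, 6)); mask[1:5, 1:5] = 1
        assert crack_perimeter(mask) == 16


class TestStatistics:
    def test_two_level_golden_values(self):
        m = np.zeros(10); m[5:] = 1
        y = statistical_features(m, levels=2)
        np.testing.assert_allclose(y, [0.5, 0.25, 0.5, 0.0, 1.0], atol=1e-12)

    def test_constant_map_degenerate(self):
        y = statistical_features(np.full((4, 4), 17.0))
        np.testing.assert_allclose(y, [17.0, 0, 0, 0, 0])

    def test_matches_bruteforce_histogram_oracle(self, rng):
        m = rng.uniform(0, 255, (24, 24))
        levels = 256
        y = statistical_features(m, levels)
        # independent oracle: explicit loop over every bin
        lo, hi = m.min(), m.max()
        q = np.rint((m.ravel() - lo) / (hi - lo) * (levels - 1)).astype(int)
        hist = np.zeros(levels)
        for v in q:
            hist[v] += 1
        hist /= q.size
        mean = sum(t * hist[t] for t in range(levels))
        var = sum((t - mean) ** 2 * hist[t] for t in range(levels))
        sd = var ** 0.5
        skew = mean ** -3 * sum((t - mean) ** 3 * hist[t] for t in range(levels))
        kurt = mean ** -4 * sum((t - mean) ** 4 * hist[t] for t in range(levels))
        np.testing.assert_allclose(y, [mean, var, sd, skew, kurt], atol=1e-9)

    def test_sd_is_sqrt_of_variance(self, rng):
        for _ in range(10):
            y = statistical_features(rng.uniform(-50, 50, (12, 12)))
            assert y[2] ** 2 == pytest.approx(y[1], abs=1e-9)


class TestAssemble:
    def test_default_vector_length_and_names(self, small_phantoms):
        s = small_phantoms[-1]
        rec = extract_features(s.image, s.mask)
        assert rec.vector.size == 5 * (16 + 1 + 4) + 4 == 109
        assert len(rec.names) == 109
        assert rec.names[0].startswith("gabor_f0.1_t0")
        assert rec.names[-4:] == ["shape_compactness", "shape_eccentricity",
                                  "shape_rectangularity", "shape_solidity"]
        assert rec.feature_image.shape == (7,) + s.image.shape
        assert not np.any(np.isnan(rec.vector))

    def test_repeat_extraction_byte_identical(self, small_phantoms):
        s = small_phantoms[-1]
        r1 = extract_features(s.image, s.mask)
        r2 = extract_features(s.image, s.mask)
        np.testing.assert_array_equal(r1.vector, r2.vector)

    def test_empty_mask_gives_zero_shape_block(self, small_phantoms):
        s = small_phantoms[-1]
        rec = extract_features(s.image, np.zeros_like(s.mask))
        np.testing.assert_array_equal(rec.vector[-4:], 0.0)

    def test_class_separability_on_phantoms(self):
        samples = generate_dataset(PhantomSpec(seed=21), 20)
        bank = FeatureBank()
        X = bank.fit_transform(samples)
        y = np.array([s.label for s in samples])
        m0, m1 = X[y == 0], X[y == 1]
        pooled = np.sqrt((m0.var(axis=0) + m1.var(axis=0)) / 2) + 1e-12
        d = np.abs(m0.mean(axis=0) - m1.mean(axis=0)) / pooled
        assert d.max() >= 0.8

    def test_solidity_in_unit_interval_for_nonempty_masks(self, small_phantoms):
        for s in small_phantoms:
            if s.mask.any():
                h = shape_features(s.mask)
                assert 0.0 < h[3] <= 1.0
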