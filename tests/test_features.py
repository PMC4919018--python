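"""Feature extractors: closed-form cases, bounds, and invariances."""

import numpy as np
import pytest

from viscomplexity import (
    FeatureConfig,
    FeatureTable,
    colorfulness,
    compression_ratio,
    edge_density,
    extract_all,
    frequency_factor,
    number_of_colors,
    to_gray,
)
from viscomplexity.features import MEASURE_NAMES

import pandas as pd


class TestToGray:
    def test_achromatic_identity(self):
        img = np.full((8, 8, 3), 128, dtype=np.uint8)
        assert np.all(to_gray(img) == 128)
        assert np.all(to_gray(np.full((8, 8, 3), 255, dtype=np.uint8)) == 255)

    def test_pure_red_luma(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert np.all(to_gray(img) == 76)  # round(0.299 * 255)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            to_gray(np.zeros((4, 4, 3), dtype=np.uint8))  # too small
        with pytest.raises(ValueError):
            to_gray(np.zeros((8, 8), dtype=np.uint8))  # not RGB


class TestFrequencyFactor:
    def test_constant_image_is_zero(self):
        assert frequency_factor(np.full((32, 32), 77.0)) == 0.0

    @pytest.mark.parametrize("k", [2, 8, 16])
    def test_pure_sinusoid_gives_its_frequency(self, k):
        w = 64
        x = np.arange(w)
        img = 128 + 100 * np.sin(2 * np.pi * k * x / w)
        img = np.tile(img, (w, 1))
        assert frequency_factor(img) == pytest.approx((k / w) / 0.5, abs=1e-9)

    def test_white_noise_matches_brute_force_scan(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(float)
        # brute-force oracle: sort every spectrum cell by radius, scan cumsum
        power = np.abs(np.fft.fft2(img)) ** 2
        power[0, 0] = 0.0
        fy = np.fft.fftfreq(32)
        fx = np.fft.fftfreq(32)
        radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2).ravel()
        order = np.argsort(radius, kind="stable")
        cum = np.cumsum(power.ravel()[order])
        expect = min(radius[order][np.searchsorted(cum, 0.99 * cum[-1])] / 0.5, 1.0)
        got = frequency_factor(img)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got > 0.8  # white noise is broadband

    def test_monotone_in_noise_amplitude(self):
        base = np.tile(np.linspace(0, 255, 64), (64, 1))
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1, (64, 64))
        vals = [
            frequency_factor(np.clip(base + amp * noise, 0, 255))
            for amp in (0.0, 10.0, 40.0)
        ]
        assert vals[0] <= vals[1] <= vals[2]


class TestEdgeDensity:
    def test_constant_image_has_no_edges(self):
        assert edge_density(np.full((32, 32), 128.0)) == 0.0

    def test_single_step_edge_density(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 255.0
        d = edge_density(img)
        assert 0.5 / 64 <= d <= 2.5 / 64  # about one edge column

    def test_bounded(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(float)
        assert 0.0 <= edge_density(img) <= 1.0


class TestCompressionRatio:
    def test_noise_compresses_worse_than_flat(self, rng):
        flat = np.full((256, 256, 3), 90, dtype=np.uint8)
        noise = rng.integers(0, 256, (256, 256, 3)).astype(np.uint8)
        r_flat = compression_ratio(flat)
        r_noise = compression_ratio(noise)
        assert 0.0 < r_flat < r_noise
        assert r_noise <= 1.5  # sanity ceiling: headers only exceed raw when tiny


class TestColorStatistics:
    def test_achromatic_colorfulness_is_zero(self, rng):
        g = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        img = np.stack([g, g, g], axis=-1)
        assert colorfulness(img) == 0.0

    def test_constant_red_closed_form(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        img[..., 0] = 255
        expected = 0.3 * np.sqrt(255.0**2 + 127.5**2)
        assert colorfulness(img) == pytest.approx(expected)

    def test_color_count_exact_and_quantized(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        grays = np.arange(256, dtype=np.uint8).reshape(16, 16)
        img[..., 0] = img[..., 1] = img[..., 2] = grays
        assert number_of_colors(img) == 256
        assert number_of_colors(img, quant_levels=4) <= 4**3
        assert number_of_colors(np.full((8, 8, 3), 9, dtype=np.uint8)) == 1


class TestExtractAll:
    def test_constant_image_identities(self, constant_gray):
        with pytest.warns(UserWarning, match="correlation"):
            fv = extract_all(constant_gray)
        assert fv.m1 == 0.0
        assert fv.m3 == 1.0
        assert fv.m4 == 1.0
        assert fv.m5 == 0.0
        assert fv.m6 == 0.0
        assert fv.m8 == 1
        assert fv.m9 == 0.0
        assert fv.m10 == 1

    def test_composition_equals_per_measure_calls(self, mosaic):
        from viscomplexity import compute_glcm, glcm_contrast, num_regions

        fv = extract_all(mosaic)
        gray = to_gray(mosaic)
        assert fv.m1 == glcm_contrast(compute_glcm(gray, 8, (0, 1)))
        assert fv.m5 == frequency_factor(gray)
        assert fv.m7 == compression_ratio(mosaic)
        assert fv.m8 == num_regions(mosaic)
        assert fv.m9 == colorfulness(mosaic)

    def test_deterministic_and_copy_invariant(self, mosaic):
        a = extract_all(mosaic).as_array()
        b = extract_all(mosaic.copy()).as_array()
        np.testing.assert_array_equal(a, b)

    def test_gray_measures_invariant_to_replicated_luma(self, mosaic):
        """M1-M6 must agree between an RGB image and its replicated luma."""
        gray = to_gray(mosaic)
        replicated = np.stack([gray, gray, gray], axis=-1)
        fa = extract_all(mosaic).as_array()
        fb = extract_all(replicated).as_array()
        np.testing.assert_allclose(fa[:6], fb[:6], atol=1e-12)


class TestNormalization:
    def _table(self, values):
        n = len(values)
        data = {c: list(values) for c in MEASURE_NAMES}
        df = pd.DataFrame(data, index=[f"i{k}" for k in range(n)])
        return FeatureTable(data=df)

    def test_min_max_scaling(self):
        t = self._table([2.0, 4.0, 6.0]).normalize()
        np.testing.assert_allclose(t.values[:, 0], [0.0, 0.5, 1.0])
        assert t.normalized

    def test_already_unit_interval_identity(self):
        t = self._table([0.0, 0.25, 1.0]).normalize()
        np.testing.assert_allclose(t.values[:, 0], [0.0, 0.25, 1.0])

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant column"):
            t = self._table([3.0, 3.0, 3.0]).normalize()
        assert np.all(t.values == 0.0)

    def test_normalize_denormalize_roundtrip(self, rng):
        vals = rng.uniform(-5, 20, size=12)
        t = self._table(list(vals))
        back = t.normalize().denormalize()
        np.testing.assert_allclose(back.values, t.values, atol=1e-9)

    def test_missing_column_named_in_error(self):
        df = pd.DataFrame({"M1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="M2"):
            FeatureTable(data=df)
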