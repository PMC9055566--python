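import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from fbastack import (
    FBAParams,
    GrayImage,
    RGBImage,
    SpectralWeights,
    fba_merge,
    fourier_weights,
    smooth_magnitude,
)


def wrapped_gaussian_kernel(n: int, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Independent oracle: sampled 1-D Gaussian, normalized, wrapped onto n bins."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    out = np.zeros(n)
    for offset, weight in zip(x, k):
        out[offset % n] += weight
    return out


class TestSmoothMagnitude:
    def test_sigma_zero_is_identity(self, rng):
        mag = rng.uniform(0, 10, size=(8, 8))
        assert np.array_equal(smooth_magnitude(mag, 0.0), mag)

    def test_constant_preserved(self):
        mag = np.full((16, 16), 3.7)
        assert np.allclose(smooth_magnitude(mag, 2.0), 3.7)

    def test_impulse_matches_wrapped_kernel(self):
        mag = np.zeros((8, 8))
        mag[0, 0] = 1.0
        out = smooth_magnitude(mag, 1.0)
        k = wrapped_gaussian_kernel(8, 1.0)
        expected = np.outer(k, k)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.isclose(out.sum(), 1.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_magnitude(np.ones((4, 4)), -1.0)


class TestFourierWeights:
    def test_p_zero_uniform(self, rng):
        mags = rng.uniform(0, 5, size=(4, 6, 6))
        w = fourier_weights(mags, 0.0).weights
        assert np.allclose(w, 0.25)

    def test_single_frame_unit_weight(self, rng):
        mags = rng.uniform(0, 5, size=(1, 6, 6))
        assert np.allclose(fourier_weights(mags, 3.0).weights, 1.0)

    @pytest.mark.parametrize("p, expected", [(1.0, (2 / 3, 1 / 3)), (2.0, (4 / 5, 1 / 5))])
    def test_hand_computed_ratio(self, p, expected):
        mags = np.stack([np.full((2, 2), 2.0), np.full((2, 2), 1.0)])
        w = fourier_weights(mags, p).weights
        assert np.allclose(w[0], expected[0])
        assert np.allclose(w[1], expected[1])

    def test_zero_magnitude_bin_uniform(self):
        mags = np.zeros((3, 2, 2))
        mags[0, 0, 0] = 1.0  # one nonzero bin; the rest are 0/0 ties
        w = fourier_weights(mags, 2.0).weights
        assert np.allclose(w[:, 0, 0], [1.0, 0.0, 0.0])
        assert np.allclose(w[:, 1, 1], 1 / 3)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            fourier_weights(np.ones((2, 4, 4)), -0.5)

    @given(
        n=st.integers(1, 5),
        p=st.floats(0.0, 50.0, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_normalization_property(self, n, p, seed):
        mags = np.random.default_rng(seed).uniform(0, 10, size=(n, 5, 5))
        w = fourier_weights(mags, p).weights
        assert w.min() >= 0
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-9)

    def test_type_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            SpectralWeights(np.full((2, 2, 2), 0.4))


class TestFBAMerge:
    @pytest.mark.parametrize("k", [1, 2, 7])
    def test_identity_on_duplicates(self, k, random_rgb):
        merged = fba_merge([random_rgb] * k, FBAParams(p=11.0, mag_sigma=2.0))
        assert np.abs(merged.pixels - random_rgb.pixels).max() < 1e-6

    def test_p_zero_is_pixelwise_mean(self, rng):
        frames = [GrayImage(rng.uniform(0, 255, size=(16, 16))) for _ in range(4)]
        merged = fba_merge(frames, FBAParams(p=0.0, mag_sigma=0.0))
        oracle = np.mean([f.pixels for f in frames], axis=0)
        assert np.abs(merged.pixels - oracle).max() < 1e-6

    def test_prefers_sharp_over_blurred(self, rng):
        sharp = np.clip(rng.uniform(20, 235, size=(64, 64)), 0, 255)
        blurred = ndimage.gaussian_filter(sharp, sigma=3.0)
        merged = fba_merge(
            [GrayImage(sharp), GrayImage(blurred)], FBAParams(p=15.0, mag_sigma=2.0)
        )
        rmse_sharp = np.sqrt(((merged.pixels - sharp) ** 2).mean())
        rmse_blur = np.sqrt(((merged.pixels - blurred) ** 2).mean())
        assert rmse_sharp < rmse_blur

    def test_large_p_approaches_argmax_reconstruction(self, rng):
        # two frames with strictly ordered spectra: B = A/2 at every bin
        a = rng.uniform(10, 245, size=(32, 32))
        b = a / 2.0
        spectra = np.fft.fft2(np.stack([a, b]), axes=(-2, -1))
        mags = np.stack([smooth_magnitude(np.abs(s), 2.0) for s in spectra])
        choice = np.argmax(mags, axis=0)
        selected = np.take_along_axis(spectra, choice[None], axis=0)[0]
        argmax_recon = np.real(np.fft.ifft2(selected))
        frames = [GrayImage(a), GrayImage(b)]
        rmses = []
        for p in (1.0, 10.0, 100.0):
            merged = fba_merge(frames, FBAParams(p=p, mag_sigma=2.0))
            rmses.append(np.sqrt(((merged.pixels - argmax_recon) ** 2).mean()))
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_dc_conservation_equal_means(self, rng):
        # frames share the same mean; mid-range values so clipping is inert
        base = rng.uniform(100, 150, size=(16, 16))
        frames = []
        for _ in range(3):
            f = rng.uniform(100, 150, size=(16, 16))
            frames.append(GrayImage(f - f.mean() + base.mean()))
        merged = fba_merge(frames, FBAParams(p=7.0, mag_sigma=1.0))
        assert abs(merged.pixels.mean() - base.mean()) < 1e-6

    def test_imaginary_residue_negligible(self, rng):
        frames = np.stack([rng.uniform(0, 255, size=(16, 16)) for _ in range(3)])
        spectra = np.fft.fft2(frames, axes=(-2, -1))
        mags = np.stack([smooth_magnitude(np.abs(s), 2.0) for s in spectra])
        w = fourier_weights(mags, 11.0).weights
        fused = np.fft.ifft2((w * spectra).sum(axis=0))
        assert np.abs(fused.imag).max() < 1e-6 * np.abs(fused.real).max()

    def test_rgb_same_shape_and_kind(self, random_rgb, rng):
        other = RGBImage(rng.integers(0, 256, size=(24, 32, 3)).astype(float))
        merged = fba_merge([random_rgb, other])
        assert isinstance(merged, RGBImage)
        assert merged.pixels.shape == random_rgb.pixels.shape

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fba_merge([])

    def test_dimension_mismatch_rejected(self, rng):
        a = GrayImage(rng.uniform(0, 255, size=(8, 8)))
        b = GrayImage(rng.uniform(0, 255, size=(8, 10)))
        with pytest.raises(ValueError):
            fba_merge([a, b])

    def test_sharpen_changes_output(self, rng):
        sharp = GrayImage(np.clip(rng.uniform(40, 215, size=(32, 32)), 0, 255))
        blurred = GrayImage(ndimage.gaussian_filter(sharp.pixels, 2.0))
        plain = fba_merge([sharp, blurred], FBAParams(sharpen=False))
        sharpened = fba_merge([sharp, blurred], FBAParams(sharpen=True))
        assert not np.allclose(plain.pixels, sharpened.pixels)


class TestFBAParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": -1.0},
            {"mag_sigma": -0.1},
            {"window_size": 0},
            {"stride": 0},
            {"stride": 300, "tile_size": 256},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FBAParams(**kwargs)

    def test_defaults(self):
        params = FBAParams()
        assert params.p == 11.0
        assert params.mag_sigma == 2.0
        assert params.window_size == 7
        assert params.tile_size == 256
        assert params.stride == 128
        assert params.sharpen is False
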