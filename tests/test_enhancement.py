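"""Percentile profiling, histogram matching, and the SNR profile."""

import warnings

import numpy as np
import pytest

from hepatovasc.enhancement import match_to_reference, percentile_profile, snr_profile
from hepatovasc.phantom import PhantomSpec, generate_phantom
from hepatovasc.volumes import BinaryVolume, IntensityVolume


def _volume(data, spacing=(1, 1, 1)):
    return IntensityVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing)


class TestPercentileProfile:
    def test_constant_volume(self):
        prof = percentile_profile(_volume(np.full((4, 8, 8), 7.0)))
        np.testing.assert_array_equal(prof.i1, np.full(4, 7.0))
        np.testing.assert_array_equal(prof.i99, np.full(4, 7.0))
        assert prof.reference_index == 0  # tie -> shallowest

    def test_widest_range_slice_wins(self):
        data = np.full((5, 16, 16), 10.0)
        data[3] = np.linspace(0, 255, 256).reshape(16, 16)
        assert percentile_profile(_volume(data)).reference_index == 3

    def test_matches_sort_based_oracle(self, rng):
        """I1/I99 agree with exhaustive order statistics on 101 values."""
        data = rng.random((6, 101, 1)) * 300
        prof = percentile_profile(_volume(data))
        for z in range(6):
            srt = np.sort(data[z].ravel())
            # linear interpolation between order statistics at p=1 and 99
            assert prof.i1[z] == pytest.approx(np.percentile(srt, 1))
            assert prof.i99[z] == pytest.approx(srt[99])  # p99 of 101 values


class TestHistogramMatching:
    def test_reference_slice_nearly_unchanged(self, rng):
        data = rng.random((4, 32, 32)) * 255
        prof = percentile_profile(_volume(data))
        matched = match_to_reference(_volume(data), prof)
        ref = prof.reference_index
        # identity up to the 256-bin quantization of the monotone map
        assert np.abs(matched.data[ref] - data[ref]).mean() < 3.0

    def test_scaled_slice_recovers_reference_multiset(self, rng):
        """A slice at half the reference's intensities maps back onto it."""
        a = rng.random((64, 64)) * 200 + 10
        data = np.stack([a, 0.5 * a])
        vol = _volume(data)
        matched = match_to_reference(vol, percentile_profile(vol))
        got = np.sort(matched.data[1].ravel())
        want = np.sort(a.ravel())
        np.testing.assert_allclose(got, want, atol=2.5)

    def test_mapping_is_monotone_within_slice(self, rng):
        data = rng.random((3, 40, 40)) * 100
        data[0] *= 3  # make slice 0 the reference
        vol = _volume(data)
        matched = match_to_reference(vol, percentile_profile(vol))
        for z in range(3):
            order = np.argsort(data[z].ravel(), kind="stable")
            mapped = matched.data[z].ravel()[order]
            assert np.all(np.diff(mapped) >= -1e-9)

    def test_idempotent_up_to_quantization(self, rng):
        data = rng.random((4, 32, 32)) * 255
        vol = _volume(data)
        once = match_to_reference(vol, percentile_profile(vol))
        twice = match_to_reference(once, percentile_profile(once))
        assert np.abs(twice.data - once.data).mean() < 3.0

    def test_degenerate_reference_passes_through_with_warning(self):
        vol = _volume(np.full((3, 8, 8), 5.0))
        with pytest.warns(UserWarning, match="zero intensity range"):
            out = match_to_reference(vol)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_preserves_shape_spacing_nonnegativity(self, rng):
        vol = _volume(rng.random((5, 24, 24)) * 80, spacing=(2.0, 0.5, 0.5))
        matched = match_to_reference(vol)
        assert matched.shape == vol.shape
        assert matched.spacing == vol.spacing
        assert matched.data.min() >= 0

    def test_deep_slice_range_grows_on_attenuated_phantom(self):
        """Matching restores dynamic range lost to exponential depth decay."""
        ph = generate_phantom(PhantomSpec(shape=(64, 96, 96), seed=3,
                                          attenuation_per_mm=2.0, noise_sd_frac=0.05))
        vol = ph.intensity
        prof = percentile_profile(vol)
        matched = match_to_reference(vol, prof)
        after = percentile_profile(matched)
        deep = np.arange(vol.shape[0]) > prof.reference_index
        occupied = prof.range_ > 1.0  # slices with any structure
        sel = deep & occupied
        assert sel.any()
        assert np.all(after.range_[sel] >= prof.range_[sel] - 1e-6)


class TestSnrProfile:
    def test_known_arithmetic(self):
        data = np.zeros((2, 10, 10))
        fg = np.zeros((2, 10, 10), dtype=bool)
        fg[0, :5] = True
        data[0][fg[0]] = 100.0
        rng = np.random.default_rng(0)
        noise = rng.normal(50, 10, size=50)
        data[0][~fg[0]] = noise
        snr = snr_profile(
            IntensityVolume(data=data, spacing=(1, 1, 1)),
            BinaryVolume(data=fg, spacing=(1, 1, 1)),
        )
        expect = 20 * np.log10(100.0 / noise.std())
        assert snr[0] == pytest.approx(expect)

    def test_all_background_slice_is_nan(self):
        data = np.ones((2, 4, 4))
        fg = np.zeros((2, 4, 4), dtype=bool)
        fg[0, 0, 0] = True
        snr = snr_profile(
            IntensityVolume(data=data, spacing=(1, 1, 1)),
            BinaryVolume(data=fg, spacing=(1, 1, 1)),
        )
        assert np.isnan(snr[1])

    def test_zero_background_variance_is_inf(self):
        data = np.zeros((2, 4, 4))
        fg = np.zeros((2, 4, 4), dtype=bool)
        fg[:, 0, 0] = True
        data[:, 0, 0] = 10.0
        snr = snr_profile(
            IntensityVolume(data=data, spacing=(1, 1, 1)),
            BinaryVolume(data=fg, spacing=(1, 1, 1)),
        )
        assert np.isposinf(snr[0])

    def test_enhancement_lifts_snr_at_depth(self):
        """With strong depth decay, matching restores the attenuated deep
        slices: their SNR improves."""
        ph = generate_phantom(PhantomSpec(shape=(96, 96, 96), seed=6,
                                          attenuation_per_mm=12.0,
                                          noise_sd_frac=0.05))
        fg = BinaryVolume(
            data=ph.vessel_truth.data | ph.sinusoid_truth.data,
            spacing=ph.intensity.spacing,
        )
        matched = match_to_reference(ph.intensity)
        before = snr_profile(ph.intensity, fg)
        after = snr_profile(matched, fg)
        nz = ph.intensity.shape[0]
        deep = np.arange(nz) >= nz // 2
        ok = np.isfinite(before) & np.isfinite(after) & deep
        assert ok.any()
        assert np.median(after[ok] - before[ok]) > 0
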