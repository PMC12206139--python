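"""Grayscale spherical erosion, the MID/IR sweep, and vessel segmentation."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from hepatovasc.phantom import PhantomSpec, dice, generate_phantom
from hepatovasc.vessels import (
    adaptive_threshold,
    ball_footprint,
    connected_components,
    erode_sphere,
    erosion_metrics,
    filter_small_components,
    segment_vessels,
    sweep_erosion_radius,
)
from hepatovasc.volumes import BinaryVolume, IntensityVolume

from .conftest import make_cylinder


def _volume(data, spacing=(1, 1, 1)):
    return IntensityVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing)


class TestErodeSphere:
    def test_constant_volume_unchanged(self):
        vol = _volume(np.full((8, 8, 8), 42.0))
        np.testing.assert_array_equal(erode_sphere(vol, 3.0).data, vol.data)

    def test_point_source_annihilated(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        assert not erode_sphere(_volume(data), 1.0).data.any()

    def test_tiny_radius_is_identity_with_warning(self, rng):
        vol = _volume(rng.random((4, 8, 8)))
        with pytest.warns(UserWarning, match="below half the voxel pitch"):
            out = erode_sphere(vol, 0.2)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_cylinder_shrinks_by_the_erosion_radius(self):
        """Eroding a 10 um cylinder with a 4 um ball leaves a ~6 um cylinder."""
        tube = make_cylinder((20, 41, 41), axis_len=20, radius=10.0, axis=0)
        eroded = erode_sphere(_volume(tube), 4.0)
        want = make_cylinder((20, 41, 41), axis_len=20, radius=6.0, axis=0) > 0
        mid = slice(5, 15)  # away from the open tube ends
        got = eroded.data[mid] > 0
        overlap = 2 * (got & want[mid]).sum() / (got.sum() + want[mid].sum())
        assert overlap > 0.9

    def test_anisotropic_ball_footprint(self):
        fp = ball_footprint(2.0, spacing=(2.0, 1.0, 1.0))
        assert fp.shape == (3, 5, 5)  # 1 voxel reach in z, 2 in y/x
        assert fp[1, 2, 2] and fp[0, 2, 2] and not fp[0, 2, 0]

    def test_monotone_in_radius(self, rng):
        vol = _volume(ndi.gaussian_filter(rng.random((12, 20, 20)) * 100, 1.5))
        e2 = erode_sphere(vol, 2.0)
        e4 = erode_sphere(vol, 4.0)
        assert np.all(e4.data <= e2.data + 1e-12)
        assert np.all(e2.data <= vol.data + 1e-12)


class TestErosionMetrics:
    def test_identity_erosion(self, rng):
        vol = _volume(rng.random((4, 6, 6)) + 0.1)
        assert erosion_metrics(vol, vol) == pytest.approx((0.0, 1.0))

    def test_total_erosion(self):
        vol = _volume(np.full((2, 2, 2), 10.0))
        zero = _volume(np.zeros((2, 2, 2)))
        assert erosion_metrics(vol, zero) == pytest.approx((10.0, 0.0))

    def test_toy_arithmetic(self):
        orig = _volume(np.full((2, 2, 2), 10.0))
        eroded = _volume(np.full((2, 2, 2), 5.0))
        assert erosion_metrics(orig, eroded) == pytest.approx((5.0, 0.5))

    def test_all_zero_original_is_an_error(self):
        zero = _volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="all-zero"):
            erosion_metrics(zero, zero)


@pytest.fixture(scope="module")
def sweep():
    ph = generate_phantom(PhantomSpec.erosion_bench(seed=7))
    return sweep_erosion_radius(ph.intensity, np.arange(1.0, 8.01, 0.5))


class TestSweep:

    def test_normalization_endpoints(self, sweep):
        assert sweep.mid_norm[0] == pytest.approx(0.0)
        assert sweep.ir_norm[0] == pytest.approx(1.0)

    def test_raw_curves_monotone(self, sweep):
        assert np.all(np.diff(sweep.mid_raw) >= -1e-9)
        assert np.all(np.diff(sweep.ir_raw) <= 1e-9)

    def test_crossing_at_the_sinusoid_scale(self, sweep):
        """4 um-diameter sinusoids put the MID/IR crossing in [3, 5] um."""
        assert sweep.crossed
        assert 3.0 <= sweep.optimal_radius_um <= 5.0

    def test_needs_three_increasing_radii(self, rng):
        vol = _volume(rng.random((4, 8, 8)) + 0.1)
        with pytest.raises(ValueError):
            sweep_erosion_radius(vol, [1.0, 2.0])
        with pytest.raises(ValueError):
            sweep_erosion_radius(vol, [1.0, 3.0, 2.0])


class TestAdaptiveThreshold:
    def test_constant_volume_yields_empty_mask(self):
        vol = _volume(np.full((4, 10, 10), 9.0))
        assert not adaptive_threshold(vol, window_um=5.0).data.any()

    def test_additive_shift_invariance_at_zero_offset(self, rng):
        data = rng.random((6, 20, 20)) * 50
        m1 = adaptive_threshold(_volume(data), window_um=7.0)
        m2 = adaptive_threshold(_volume(data + 30.0), window_um=7.0)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_window_larger_than_volume_uses_global_mean(self):
        data = np.zeros((4, 6, 6))
        data[0, 0, 0] = 60.0
        mask = adaptive_threshold(_volume(data), window_um=1000.0)
        assert mask.data[0, 0, 0]
        assert mask.data.sum() == 1


class TestSegmentVessels:
    def test_bright_tube_on_dark_background(self):
        """A 20 um tube segments with Dice >= 0.9 at default settings."""
        tube = make_cylinder((30, 61, 61), axis_len=30, radius=10.0, axis=0)
        truth = tube > 0
        mask = segment_vessels(_volume(tube), window_um=25.0)
        assert dice(mask.data, truth) >= 0.9

    def test_pipeline_is_deterministic(self, rng):
        data = ndi.gaussian_filter(rng.random((10, 24, 24)) * 120, 1.0)
        a = segment_vessels(_volume(data))
        b = segment_vessels(_volume(data))
        np.testing.assert_array_equal(a.data, b.data)


class TestComponentFilter:
    @staticmethod
    def _mask_with_sizes(sizes):
        """Disjoint axis-aligned bars of the given voxel counts."""
        data = np.zeros((4, 10 * len(sizes), max(sizes) + 2), dtype=bool)
        for i, s in enumerate(sizes):
            data[1, 10 * i + 3, 1:1 + s] = True
        return BinaryVolume(data=data, spacing=(1, 1, 1))

    def test_spec_example_1_2_100(self):
        mask = self._mask_with_sizes([1, 2, 100])
        out = filter_small_components(mask, cap_fraction=None)
        _, n = connected_components(out)
        assert n == 2
        assert int(out.data.sum()) == 102  # the 1-voxel component is gone

    def test_single_component_survives(self):
        mask = self._mask_with_sizes([17])
        out = filter_small_components(mask)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_empty_mask_passes_through(self):
        mask = BinaryVolume(data=np.zeros((3, 4, 4), dtype=bool), spacing=(1, 1, 1))
        assert not filter_small_components(mask).data.any()

    def test_matches_brute_force_enumeration(self, rng):
        """Survivors equal a label-and-sort oracle on ~50 random components."""
        sizes = list(rng.integers(1, 30, size=50))
        mask = self._mask_with_sizes(sizes)
        labels, n = connected_components(mask)
        counts = np.bincount(labels.ravel())[1:]
        median = np.median(counts)
        want = {i + 1 for i, c in enumerate(counts) if c >= median}
        out = filter_small_components(mask, cap_fraction=None)
        got = set(np.unique(labels[out.data]))
        assert got == want

    def test_cap_protects_a_handful_of_true_vessels(self):
        """Three vessel-sized components with no fragments all survive."""
        mask = self._mask_with_sizes([80, 100, 120])
        out = filter_small_components(mask)  # default cap
        _, n = connected_components(out)
        assert n == 3
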