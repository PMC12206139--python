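"""Skeletonization, graph decomposition, and the morphometric statistics."""

import numpy as np
import pytest

from hepatovasc.morphometry import (
    build_graph,
    relative_change_table,
    sinusoid_density,
    sinusoid_metrics,
    skeletonize,
    vessel_count_ratio,
)
from hepatovasc.volumes import BinaryVolume

from .conftest import make_cylinder


def _mask(data, spacing=(1, 1, 1)):
    return BinaryVolume(data=np.asarray(data, dtype=bool), spacing=spacing)


class TestSkeletonize:
    def test_straight_tube_thins_to_a_single_path(self):
        tube = make_cylinder((100, 15, 15), axis_len=100, radius=3.0, axis=0) > 0
        skel = skeletonize(_mask(tube))
        graph = build_graph(skel)
        assert graph.n_components == 1
        assert len(graph.branches) == 1
        assert abs(skel.data.sum() - 100) <= 3

    def test_solid_ball_leaves_almost_nothing(self):
        zz, yy, xx = np.indices((21, 21, 21))
        ball = ((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2) <= 64
        skel = skeletonize(_mask(ball))
        assert skel.data.sum() <= 10  # no elongation to trace

    def test_two_tubes_two_components(self):
        # odd cross-sections: Lee thinning erases even-width bars outright
        data = np.zeros((40, 30, 30), dtype=bool)
        data[5:35, 5:10, 5:10] = True
        data[5:35, 20:25, 20:25] = True
        graph = build_graph(skeletonize(_mask(data)))
        assert graph.n_components == 2

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize(_mask(np.zeros((4, 4, 4))))
        assert not skel.data.any()


class TestBuildGraph:
    def test_straight_eleven_voxel_path(self):
        data = np.zeros((3, 3, 13), dtype=bool)
        data[1, 1, 1:12] = True
        graph = build_graph(_mask(data))
        assert len(graph.nodes) == 2
        assert all(d == 1 for d in graph.nodes.values())
        assert len(graph.branches) == 1
        assert graph.branches[0].length_um == pytest.approx(10.0)
        assert graph.branches[0].straightness == pytest.approx(1.0)

    def test_y_shape(self):
        # arms leave the center in pairwise non-adjacent directions
        # (26-connectivity makes orthogonal first steps touch diagonally)
        data = np.zeros((3, 25, 25), dtype=bool)
        c = (1, 12, 12)
        for k in range(1, 11):
            data[1, 12, 12 + k] = True          # east arm
            data[1, 12 + k, 12 - k] = True      # south-west diagonal arm
            data[1, 12 - k, 12 - k] = True      # north-west diagonal arm
        data[c] = True
        graph = build_graph(_mask(data))
        assert len(graph.junctions) == 1
        assert len(graph.endpoints) == 3
        assert len(graph.branches) == 3

    def test_anisotropic_lengths(self):
        data = np.zeros((6, 3, 3), dtype=bool)
        data[0:6, 1, 1] = True
        graph = build_graph(_mask(data, spacing=(2.0, 1.0, 1.0)))
        assert graph.branches[0].length_um == pytest.approx(10.0)

    def test_branch_decomposition_covers_every_voxel(self, noisy_result):
        """On a real mesh skeleton, branches partition the voxel set.

        Every skeleton voxel appears in some branch path (or is an isolated
        node), branch ends are nodes, and path length bounds the chord.
        """
        graph = noisy_result.graph
        covered = set()
        for b in graph.branches:
            assert tuple(b.path[0]) in graph.nodes
            assert tuple(b.path[-1]) in graph.nodes
            assert b.length_um >= b.chord_um - 1e-9
            covered.update(map(tuple, b.path))
        covered.update(graph.nodes)
        assert len(covered) == graph.n_skeleton_voxels

    def test_pure_cycle_gets_a_node(self):
        data = np.zeros((3, 10, 10), dtype=bool)
        data[1, 2:8, 2] = True
        data[1, 2:8, 7] = True
        data[1, 2, 2:8] = True
        data[1, 7, 2:8] = True
        graph = build_graph(_mask(data))
        assert len(graph.nodes) >= 1  # an arbitrary voxel promoted to node
        covered = set(graph.nodes)
        for b in graph.branches:
            covered.update(map(tuple, b.path))
        assert len(covered) == graph.n_skeleton_voxels


class TestMetrics:
    def test_cylinder_radius_and_length_recovery(self):
        tube = make_cylinder((100, 15, 15), axis_len=100, radius=3.0, axis=0) > 0
        mask = _mask(tube)
        graph = build_graph(skeletonize(mask))
        m = sinusoid_metrics(mask, graph)
        assert 95 <= m.length_um <= 105
        assert 2.5 <= m.radius_um <= 3.5

    def test_semicircle_tortuosity_approaches_two_over_pi(self):
        """Chord over arc length of a half circle is 2/pi ~ 0.637."""
        from .conftest import digital_semicircle

        graph = build_graph(_mask(digital_semicircle(60)))
        assert len(graph.branches) == 1
        assert graph.branches[0].straightness == pytest.approx(2 / np.pi, rel=0.06)  # ~5% digital-length bias

    def test_radius_scales_with_spacing(self):
        tube = make_cylinder((50, 15, 15), axis_len=50, radius=3.0, axis=0) > 0
        m1 = sinusoid_metrics(_mask(tube), build_graph(skeletonize(_mask(tube))))
        mask2 = _mask(tube, spacing=(2.0, 2.0, 2.0))
        m2 = sinusoid_metrics(mask2, build_graph(skeletonize(mask2)))
        assert m2.radius_um == pytest.approx(2 * m1.radius_um)

    def test_tortuosity_bounded_by_one(self, noisy_result):
        assert 0 < noisy_result.metrics.tortuosity <= 1.0


class TestDensity:
    def test_arithmetic(self):
        assert sinusoid_density(10, 20, 120) == pytest.approx(0.1)
        assert sinusoid_density(0, 20, 120) == 0.0

    def test_undefined_when_vessels_fill_the_volume(self):
        assert np.isnan(sinusoid_density(1.0, 120.0, 120.0))

    def test_matches_voxel_count_oracle_on_phantom(self, clean_phantom):
        ph = clean_phantom
        v_s = ph.sinusoid_truth.data.sum() * ph.sinusoid_truth.voxel_volume_um3
        v_l = ph.vessel_truth.data.sum() * ph.vessel_truth.voxel_volume_um3
        v = np.prod(ph.spec.shape) * ph.sinusoid_truth.voxel_volume_um3
        assert sinusoid_density(v_s, v_l, v) == pytest.approx(
            ph.realized["sinusoid_density"]
        )


class TestVesselCountRatio:
    def test_normalizes_by_the_maximum(self):
        np.testing.assert_allclose(vessel_count_ratio([3, 6, 2]), [0.5, 1.0, 1 / 3])

    def test_single_dataset(self):
        assert vessel_count_ratio([5]) == pytest.approx([1.0])

    def test_permutation_equivariance(self, rng):
        counts = rng.integers(1, 20, size=6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            vessel_count_ratio(counts[perm]), vessel_count_ratio(counts)[perm]
        )


class TestRelativeChange:
    def test_identical_pairs_are_zero_change(self):
        cmp = relative_change_table([(1.0, 1.0), (2.0, 2.0)])
        assert cmp.mean_pct == 0.0
        assert cmp.sd_pct == 0.0

    def test_direction_flags(self):
        assert relative_change_table([(1.0, 2.0), (1.0, 3.0)]).label == "increase"
        assert relative_change_table([(2.0, 1.0), (3.0, 1.0)]).label == "decrease"

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            relative_change_table([(0.0, 1.0)])

    def test_larger_denominator_convention(self):
        # |a-b|/max(a,b): symmetric in the pair ordering
        a = relative_change_table([(4.0, 5.0)]).mean_pct
        b = relative_change_table([(5.0, 4.0)]).mean_pct
        assert a == b == pytest.approx(20.0)
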