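"""Topography metrics against hand computations and brute-force oracles:
vertex weights, weighted relative distances, slopes and their exact test,
preferred-duration profiles, centroids, and map comparison."""

import numpy as np
import pytest
from scipy import stats

from _oracles import (brute_force_kendall, brute_force_signed_rank_p,
                      brute_force_wrd, lmap)
from chronomap.topography import test_slopes as slope_sign_test
from chronomap.topography import (BorderGeometry, Centroid, compare_maps,
                                  correlate_slope_behavior, fit_wrd_slope,
                                  preferred_duration_profile,
                                  quantify_topography,
                                  vertex_weights, weighted_centroids,
                                  weighted_relative_distance, wrd_by_label)


# ----------------------------------------------------------------- tests

class TestVertexWeights:
    def test_isolated_voxel_has_zero_weight(self):
        arr = np.full((5, 5), np.nan)
        arr[2, 2] = 0.4
        w = vertex_weights(lmap(arr), 0.4)
        assert w[2, 2] == 0.0

    def test_two_adjacent_voxels(self):
        arr = np.full((4, 4), np.nan)
        arr[1, 1] = arr[1, 2] = 0.2
        w = vertex_weights(lmap(arr), 0.2)
        assert w[1, 1] == w[1, 2] == 0.5

    def test_solid_block_center(self):
        arr = np.full((5, 5), np.nan)
        arr[1:4, 1:4] = 0.6
        w = vertex_weights(lmap(arr), 0.6)
        assert w[2, 2] == pytest.approx(4 / 9)

    def test_absent_label_rejected(self):
        arr = np.full((3, 3), np.nan)
        arr[0, 0] = 0.2
        with pytest.raises(ValueError, match="absent"):
            vertex_weights(lmap(arr), 0.4)

    def test_weights_bounded(self, rng):
        arr = rng.choice([0.2, 0.4, np.nan], size=(6, 6, 3))
        labels = lmap(arr)
        for v in labels.present_labels():
            w = vertex_weights(labels, v)
            assert (w >= 0).all() and (w <= 1).all()


class TestWeightedRelativeDistance:
    GEOM = BorderGeometry(axis=0, d1_border=0.0, d2_border=11.0)

    def test_cluster_on_reference_border(self):
        arr = np.full((12, 12), np.nan)
        arr[0, 3:7] = 0.2
        assert weighted_relative_distance(lmap(arr), self.GEOM, 0.2) == 0.0

    def test_two_adjacent_voxels_mid_map(self):
        geom = BorderGeometry(axis=0, d1_border=0.0, d2_border=2.0)
        arr = np.full((3, 3), np.nan)
        arr[1, 0] = arr[1, 1] = 0.4      # RD = 0.5 each, w = 1/2 each
        assert weighted_relative_distance(lmap(arr), geom, 0.4) == \
            pytest.approx(0.25)

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(10):
            arr = rng.choice([0.2, 0.4, 0.6, 1.0, np.nan], size=(12, 12),
                             p=[0.2, 0.2, 0.2, 0.2, 0.2])
            labels = lmap(arr)
            for v in labels.present_labels():
                ours = weighted_relative_distance(labels, self.GEOM, v)
                ref = brute_force_wrd(arr, v, 0, 0.0, 11.0, 1.0)
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_voxel_outside_borders_rejected(self):
        geom = BorderGeometry(axis=0, d1_border=0.0, d2_border=5.0)
        arr = np.full((12, 3), np.nan)
        arr[8, 0] = 0.2
        with pytest.raises(ValueError, match="outside"):
            weighted_relative_distance(lmap(arr), geom, 0.2)


class TestSlopes:
    def test_closed_form_four_points(self):
        s = fit_wrd_slope([(0.2, 0.9), (0.4, 0.6), (0.6, 0.3), (1.0, 0.0)])
        assert s.slope_rank == pytest.approx(-0.3)

    def test_constant_is_flat(self):
        s = fit_wrd_slope([(0.2, 0.5), (0.4, 0.5), (0.6, 0.5)])
        assert s.slope_rank == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decrease_is_negative(self):
        s = fit_wrd_slope([(0.2, 0.8), (0.4, 0.5), (0.6, 0.45), (1.0, 0.1)])
        assert s.slope_rank < 0

    def test_split_slopes(self):
        pairs = [(0.2, 0.8), (0.6, 0.4), (1.0, 0.2), (1.5, 0.3), (2.0, 0.5)]
        s = fit_wrd_slope(pairs, split_at=1.0)
        assert s.sub_slope < 0 < s.supra_slope

    def test_single_point_segment_flagged(self):
        s = fit_wrd_slope([(0.2, 0.8)])
        assert s.slope_rank is None and s.n_points == 1


class TestSlopeSignTest:
    def test_all_negative_ten_subjects(self):
        slopes = -np.linspace(0.01, 0.1, 10)
        res = slope_sign_test(slopes)
        assert res.p_value == pytest.approx(2 ** -10)

    def test_symmetric_slopes_near_half(self):
        slopes = [-0.3, 0.3, -0.2, 0.2, -0.1, 0.1]
        res = slope_sign_test(slopes)
        assert 0.3 < res.p_value < 0.7

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            slopes = rng.normal(-0.02, 0.05, size=8)
            res = slope_sign_test(slopes)
            assert res.p_value == pytest.approx(
                brute_force_signed_rank_p(slopes), abs=1e-12)

    def test_zeros_dropped_and_reported(self):
        res = slope_sign_test([-0.1, -0.2, 0.0, -0.3, -0.4, -0.5])
        assert res.n_zeros_dropped == 1 and res.n_used == 5

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            slope_sign_test([-0.1, -0.2, -0.3])


class TestPreferredDurationProfile:
    def test_majority_and_tie_rules(self):
        geom = BorderGeometry(axis=0, d1_border=0.0, d2_border=5.0,
                              voxel_size=1.0)
        arr = np.full((6, 3), np.nan)
        arr[0] = [0.6, 0.6, 0.6]          # unanimous
        arr[2] = [0.2, 0.2, 1.0]          # majority
        arr[4] = [0.2, 1.0, np.nan]       # tie -> shorter
        rd, pd_ = preferred_duration_profile(lmap(arr), geom, bin_width=1.0,
                                             reduce_every=1)
        assert list(pd_) == [0.6, 0.2, 0.2]
        assert all(0 <= r <= 1 for r in rd)

    def test_average_of_five_reduction(self):
        geom = BorderGeometry(axis=0, d1_border=0.0, d2_border=9.0)
        arr = np.full((10, 1), np.nan)
        arr[:, 0] = np.linspace(0.2, 1.0, 10)
        labels = lmap(arr)
        rd, pd_ = preferred_duration_profile(labels, geom, bin_width=1.0)
        assert len(rd) == 2 and len(pd_) == 2

    def test_profile_non_decreasing_on_perfect_gradient(self):
        geom = BorderGeometry(axis=0, d1_border=0.0, d2_border=19.0)
        arr = np.repeat(np.linspace(0.2, 1.0, 20)[:, None], 4, axis=1)
        rd, pd_ = preferred_duration_profile(lmap(arr), geom, bin_width=1.5)
        assert (np.diff(pd_) >= -1e-12).all()

    def test_empty_map_rejected(self):
        geom = BorderGeometry(axis=0, d1_border=0.0, d2_border=3.0)
        with pytest.raises(ValueError, match="no labeled"):
            preferred_duration_profile(lmap(np.full((4, 4), np.nan)), geom)


class TestWeightedCentroids:
    def test_single_voxel_falls_back_to_position(self):
        arr = np.full((6, 6, 6), np.nan)
        arr[3, 4, 5] = 0.2
        cents = weighted_centroids(lmap(arr))
        assert np.allclose(cents[0.2].position_mm, [3, 4, 5])
        assert cents[0.2].fallback_unweighted

    def test_weighted_mean_arithmetic(self):
        # weights 1 and 3 at x = 0 and x = 4 -> centroid x = 3
        arr = np.full((6, 1), np.nan)
        arr[0] = arr[1] = 0.4             # voxel 0: 1 neighbor
        arr[3] = arr[4] = arr[5] = 0.4    # interior voxel 4: 2 neighbors
        cents = weighted_centroids(lmap(arr))
        x = [0, 1, 3, 4, 5]
        n = [1, 1, 1, 2, 1]
        expected = np.average(x, weights=n)
        assert cents[0.4].position_mm[0] == pytest.approx(expected)

    def test_uniform_weights_equal_plain_mean(self, rng):
        # a full block: interior weighting is symmetric along each axis,
        # so the centroid equals the arithmetic mean by symmetry
        arr = np.full((7, 7), np.nan)
        arr[2:5, 2:5] = 0.6
        cents = weighted_centroids(lmap(arr))
        coords = np.argwhere(np.isclose(arr, 0.6)).mean(axis=0)
        assert np.allclose(cents[0.6].position_mm, coords)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_centroids(lmap(np.full((3, 3), np.nan)))


class TestCompareMaps:
    GEOM = BorderGeometry(axis=0, d1_border=0.0, d2_border=9.0)

    def _map(self, shift=0):
        arr = np.full((10, 10), np.nan)
        arr[1 + shift:3 + shift, 2:5] = 0.2
        arr[5 + shift:7 + shift, 2:5] = 0.6
        return lmap(arr, voxel_size=2.0)

    def test_identical_maps(self):
        cmp = compare_maps(self._map(), self.GEOM, self._map(), self.GEOM)
        assert all(v == 1.0 for v in cmp.label_overlap.values())
        for d in cmp.centroid_border_distance_a:
            assert cmp.centroid_border_distance_a[d] == \
                cmp.centroid_border_distance_b[d]

    def test_translation_shifts_centroids(self):
        cmp = compare_maps(self._map(), self.GEOM, self._map(shift=2),
                           self.GEOM)
        for d in cmp.centroid_border_distance_a:
            shift = (cmp.centroid_border_distance_b[d]
                     - cmp.centroid_border_distance_a[d])
            assert shift == pytest.approx(2 * 2.0)

    def test_disjoint_voxel_sets_overlap_zero(self):
        cmp = compare_maps(self._map(), self.GEOM, self._map(shift=3),
                           self.GEOM)
        assert cmp.label_overlap[0.2] == 0.0

    def test_cluster_size_proportions(self):
        cmp = compare_maps(self._map(), self.GEOM, self._map(), self.GEOM)
        assert cmp.cluster_proportions_a[0.2] == pytest.approx(0.5)
        assert sum(cmp.cluster_proportions_a.values()) == pytest.approx(1.0)


class TestBehaviorCorrelation:
    def test_perfectly_concordant(self):
        res = correlate_slope_behavior([-0.5, -0.4, -0.3, -0.2, -0.1],
                                       [0.1, 0.2, 0.3, 0.4, 0.5])
        assert res["accuracy"].tau == pytest.approx(1.0)

    def test_perfectly_discordant(self):
        res = correlate_slope_behavior([-0.5, -0.4, -0.3, -0.2, -0.1],
                                       [0.9, 0.8, 0.7, 0.6, 0.5])
        assert res["accuracy"].tau == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle(self, rng):
        slopes = rng.normal(size=6)
        acc = rng.uniform(size=6)
        res = correlate_slope_behavior(slopes, acc)
        assert res["accuracy"].tau == pytest.approx(
            brute_force_kendall(slopes, acc), abs=1e-12)

    def test_constant_input_flagged(self):
        res = correlate_slope_behavior([-0.1] * 6, [0.5, 0.6, 0.7, 0.8,
                                                    0.9, 1.0])
        assert res["accuracy"].tau is None and res["accuracy"].flagged


class TestEndToEndTopography:
    def test_wrd_strictly_decreasing_on_noise_free_gradient(self):
        from chronomap.pipeline import simulate_subject_labelmap
        labels, truth = simulate_subject_labelmap(
            seed=5, shape=(16, 8, 1), sigma_star=0.15, white_sd=0.0,
            drift_amplitude=0.0)
        wrd = wrd_by_label(labels, truth.geometry())
        vals = [wrd[d] for d in sorted(wrd)]
        assert len(vals) == 4 and all(np.diff(vals) < 0)

    def test_quantify_report_roundtrip(self):
        from chronomap.pipeline import simulate_subject_labelmap
        labels, truth = simulate_subject_labelmap(seed=8, shape=(12, 6, 1))
        report = quantify_topography(labels, truth.geometry(), split_at=1.0)
        d = report.to_dict()
        assert set(d["wrd"]) <= {"0.2", "0.4", "0.6", "1"}
        assert report.slopes.slope_rank < 0
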