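"""Cluster tuning analysis: the normalization contract, offset-aligned
response extraction, PD-relative profiles, and cycle waveforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronomap.design import ScanGrid, build_exp1_design, build_exp2_design
from chronomap.simulate import TruthMap, simulate_bold
from chronomap.tuning import (NormalizedTrace, compare_pd_groups,
                              cycle_timecourse, extract_response,
                              group_durations_to_pairs, normalize_bold,
                              tuning_profile)


class TestNormalizeBold:
    def test_unit_sd_contract(self, rng):
        runs = [100 + rng.normal(0, 3, size=(6, 80)) for _ in range(3)]
        trace = normalize_bold(runs)
        assert np.std(trace.values) == pytest.approx(1.0, abs=1e-10)
        assert trace.n_runs == 3 and trace.n_voxels == 6

    def test_constant_signal_rejected(self):
        runs = [np.full((2, 50), 100.0)] * 2
        with pytest.raises(ValueError, match="zero-variance"):
            normalize_bold(runs)

    def test_zero_baseline_rejected(self):
        runs = [np.zeros((2, 50))]
        with pytest.raises(ValueError, match="zero baseline"):
            normalize_bold(runs)

    def test_two_run_one_voxel_hand_computation(self):
        r1 = np.array([[100.0, 110.0, 90.0, 100.0]])
        r2 = np.array([[102.0, 98.0, 104.0, 96.0]])
        mb = np.concatenate([r1, r2], axis=1).mean()
        rel = (np.stack([r1[0], r2[0]]) - mb) / mb
        mean_trace = rel.mean(axis=0)
        expected = mean_trace / mean_trace.std()
        trace = normalize_bold([r1, r2])
        assert np.allclose(trace.values, expected, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=50),
           seed=st.integers(min_value=0, max_value=100))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        runs = [100 + rng.normal(0, 2, size=(3, 40)) for _ in range(2)]
        a = normalize_bold(runs)
        b = normalize_bold([scale * r for r in runs])
        assert np.allclose(a.values, b.values, atol=1e-8)


class TestExtractResponse:
    def _trace(self, per_run):
        per_run = np.asarray(per_run, float)
        return NormalizedTrace(values=per_run.mean(axis=0), per_run=per_run,
                               n_runs=per_run.shape[0], n_voxels=1)

    def test_lagged_volume_indexing(self):
        events = pd.DataFrame(dict(onset=[9.5], duration=[0.5],
                                   duration_label=[0.5], role=["S1"]))
        scan = ScanGrid(tr=2.0, n_volumes=12)
        series = np.zeros((1, 12))
        series[0, 7] = 4.2                 # floor(10/2) + 2
        resp = extract_response(self._trace(series), events, scan)
        assert resp.mean[0.5] == 4.2

    def test_event_past_run_end_dropped(self):
        events = pd.DataFrame(dict(onset=[9.5, 21.0], duration=[0.5, 0.5],
                                   duration_label=[0.5, 0.5],
                                   role=["S1", "S1"]))
        scan = ScanGrid(tr=2.0, n_volumes=12)
        with pytest.warns(UserWarning, match="dropped"):
            resp = extract_response(self._trace(np.ones((1, 12))), events,
                                    scan)
        assert resp.counts[0.5] == 1

    def test_matched_cluster_prefers_its_duration(self, exp1_runs):
        # a 0.2-s-preferring cluster responds more when 0.2 s is shown
        truth = TruthMap(shape=(4,), voxel_size=2.0,
                         mu_star=np.full(4, 0.2), sigma_star=np.full(4, 0.2),
                         amplitude=np.ones(4), baseline=np.full(4, 100.0),
                         border_high=3)
        bolds = [simulate_bold(truth, ev, sc, include_s2=False)
                 for ev, sc in exp1_runs]
        trace = normalize_bold(bolds)
        resp = extract_response(trace, [ev for ev, _ in exp1_runs],
                                [sc for _, sc in exp1_runs])
        assert resp.mean[0.2] > resp.mean[1.0]


class TestGrouping:
    def test_shared_durations_feed_two_pairs(self):
        responses = {round(d, 9): 1.0 for d in
                     [0.2, 0.3, 0.4, 0.6, 0.9, 1.2, 1.8]}
        grouped = group_durations_to_pairs(responses)
        assert set(grouped) == {1, 2, 3, 4, 6, 9}
        # pair 3 is (0.6, 0.9): both present
        assert grouped[3] == 1.0

    def test_occurrence_weighting(self):
        responses = {0.4: 2.0, 0.6: 1.0}
        grouped = group_durations_to_pairs(responses, counts={0.4: 3, 0.6: 1})
        assert grouped[2] == pytest.approx((2.0 * 3 + 1.0) / 4)


class TestTuningProfile:
    def _responses(self, sigma=0.3):
        durs = [0.2, 0.4, 0.6, 1.0]
        return {pd_: {d: float(np.exp(-(d - pd_) ** 2 / (2 * sigma ** 2)))
                      for d in durs} for pd_ in durs}

    def test_pd_normalized_profile_is_one_at_pd(self):
        prof = tuning_profile(self._responses(), normalize="pd")
        for i, cluster in enumerate(prof.matrix.index):
            assert prof.matrix.iloc[i, prof.pd_index[cluster]] == 1.0

    def test_profile_peaks_at_pd(self):
        prof = tuning_profile(self._responses(), normalize="none")
        mat = prof.matrix.to_numpy()
        assert all(np.argmax(mat[i]) == prof.pd_index[c]
                   for i, c in enumerate(prof.matrix.index))

    def test_noise_free_profiles_non_increasing_with_distance(self):
        prof = tuning_profile(self._responses(sigma=0.3), normalize="pd")
        mat = prof.matrix.to_numpy()
        for i, cluster in enumerate(prof.matrix.index):
            j = prof.pd_index[cluster]
            left = mat[i, : j + 1]
            right = mat[i, j:]
            assert (np.diff(left) >= -1e-12).all()
            assert (np.diff(right) <= 1e-12).all()

    def test_zero_pd_response_rejected(self):
        responses = {0.2: {0.2: 0.0, 0.4: 1.0}}
        with pytest.raises(ValueError, match="zero response"):
            tuning_profile(responses, normalize="pd")

    def test_exp2_grouping_collapses_to_pairs(self):
        durs = [0.2, 0.3, 0.4, 0.6, 0.8, 0.9, 1.0, 1.2, 1.4, 1.5, 1.6, 1.8,
                2.0, 2.1, 2.4, 2.7, 3.0]
        responses = {0.2: {d: 1.0 / (1 + abs(d - 0.2)) for d in durs}}
        prof = tuning_profile(responses, grouping=True, normalize="none")
        assert list(prof.matrix.columns) == list(range(1, 11))
        assert prof.pd_index[0.2] == 0


class TestComparePDGroups:
    def _peaked_profiles(self, n=10, sigma=0.3):
        durs = [0.2, 0.4, 0.6, 1.0]
        profs = []
        for k in range(n):
            responses = {pd_: {d: float(np.exp(-(d - pd_) ** 2
                                               / (2 * sigma ** 2)))
                               for d in durs} for pd_ in durs}
            profs.append(tuning_profile(responses, normalize="pd"))
        return profs

    def test_peaked_profiles_significant(self):
        res = compare_pd_groups(self._peaked_profiles(10))
        assert res.p_pd_vs_pd1 < 0.05 and res.p_pd_vs_pd2 < 0.05

    def test_flat_profiles_not_significant(self):
        durs = [0.2, 0.4, 0.6, 1.0]
        rng = np.random.default_rng(3)
        profs = []
        for _ in range(10):
            responses = {pd_: {d: 1.0 + rng.normal(0, 0.05) for d in durs}
                         for pd_ in durs}
            profs.append(tuning_profile(responses, normalize="none"))
        res = compare_pd_groups(profs)
        assert res.p_pd_vs_pd1 > 0.05

    def test_single_observation_flagged(self):
        res = compare_pd_groups(self._peaked_profiles(1)[:1], min_n=5)
        assert res.flagged is None or res.n >= 5 or res.p_pd_vs_pd1 is None

    def test_union_scheme_runs(self):
        res = compare_pd_groups(self._peaked_profiles(10), scheme="union")
        assert res.p_pd_vs_pd2 < 0.05


class TestCycleTimecourse:
    def test_reshape_and_average(self):
        per_run = np.tile(np.arange(22.0), 10)[None, :]
        trace = NormalizedTrace(values=per_run[0], per_run=per_run,
                                n_runs=1, n_voxels=1)
        scan = ScanGrid(tr=2.0, n_volumes=220, direction="ascending")
        wave = cycle_timecourse(trace, scan)
        assert wave.shape == (22,)
        assert np.allclose(wave, np.arange(22.0))

    def test_descending_cycles_time_reversed(self):
        per_run = np.tile(np.arange(22.0), 10)[None, :]
        trace = NormalizedTrace(values=per_run[0], per_run=per_run,
                                n_runs=1, n_voxels=1)
        scan = ScanGrid(tr=2.0, n_volumes=220, direction="descending")
        wave = cycle_timecourse(trace, scan)
        assert np.allclose(wave, np.arange(22.0)[::-1])

    def test_non_divisible_length_rejected(self):
        per_run = np.zeros((1, 220))
        trace = NormalizedTrace(values=per_run[0], per_run=per_run,
                                n_runs=1, n_voxels=1)
        scan = ScanGrid(tr=2.0, n_volumes=220)
        with pytest.raises(ValueError, match="divisible"):
            cycle_timecourse(trace, scan, cycle_len_volumes=21)

    def test_short_pd_cluster_peaks_before_long_pd_cluster(self):
        ev, sc = build_exp2_design("ascending", 10, seed=1)
        truth = TruthMap(shape=(8,), voxel_size=2.0,
                         mu_star=np.array([0.2] * 4 + [3.0] * 4),
                         sigma_star=np.full(8, 0.4), amplitude=np.ones(8),
                         baseline=np.full(8, 100.0), border_high=7)
        bold = simulate_bold(truth, ev, sc, include_s2=False)
        waves = []
        for sel in (slice(0, 4), slice(4, 8)):
            mask = np.zeros(8, bool)
            mask[sel] = True
            trace = normalize_bold([bold], voxels=mask)
            waves.append(cycle_timecourse(trace, sc))
        assert np.argmax(waves[0]) < np.argmax(waves[1])
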