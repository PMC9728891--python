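"""Spatiotemporal-stage tests: normalization, FIR, consensus binning."""

import numpy as np
import pandas as pd
import pytest

from neurodyn import prep, synth
from neurodyn import spatiotemporal as st
from tests.conftest import TR, make_series


def _trials(rts, responses=None):
    rts = list(rts)
    onsets = 10.0 + np.concatenate(([0.0], np.cumsum(rts[:-1])))
    return pd.DataFrame({"onset": onsets, "duration": rts,
                         "response": responses or ["yes"] * len(rts)})


def _series_for(trials, n_roi=2, seed=0, tail=5.0):
    total = (trials["onset"] + trials["duration"]).iloc[-1] + tail
    n = int(np.ceil(total / TR))
    return make_series(np.random.default_rng(seed).standard_normal((n_roi, n)))


class TestPercentTime:
    def test_percent_of_decision_maps_to_seconds(self):
        assert st.percent_to_seconds(10, 45.0) == pytest.approx(4.5)
        assert st.percent_to_seconds(40, 10.0) == pytest.approx(4.0)


class TestNormalizeTrials:
    def test_mean_rt_sets_trial_length(self):
        # subject mean RT 16.35 s at TR 0.545 -> 30 samples
        trials = _trials([16.35, 16.35])
        norm = st.normalize_trials(_series_for(trials), trials)
        assert norm.trial_length == 30

    def test_equal_length_trials_identity_resampling(self):
        rt = 20 * TR
        trials = _trials([rt, rt, rt])
        series = _series_for(trials, seed=2)
        norm = st.normalize_trials(series, trials)
        assert norm.trial_length == 20
        for k, (_, trial) in enumerate(trials.iterrows()):
            i0 = int(round(trial["onset"] / TR))
            assert np.allclose(norm.segment(k), series.data[:, i0:i0 + 20])

    def test_linear_ramp_resampled_stays_linear_with_endpoints(self):
        trials = _trials([10 * TR, 30 * TR])
        n = int(np.ceil(((trials["onset"] + trials["duration"]).iloc[-1] + 3) / TR))
        ramp = np.zeros((1, n))
        i0 = int(round(trials["onset"].iloc[0] / TR))
        ramp[0, i0:i0 + 10] = np.linspace(0.0, 9.0, 10)
        norm = st.normalize_trials(make_series(ramp), trials)
        seg = norm.segment(0)[0]
        assert seg[0] == pytest.approx(0.0)
        assert seg[-1] == pytest.approx(9.0)
        assert np.allclose(np.diff(seg, 2), 0.0, atol=1e-9)

    def test_condition_filter_selects_labels(self):
        trials = _trials([15.0, 15.0, 15.0], ["yes", "no", "yes"])
        norm = st.normalize_trials(_series_for(trials), trials, "yes")
        assert norm.labels == ("yes", "yes")
        with pytest.raises(ValueError, match="unknown condition"):
            st.normalize_trials(_series_for(trials), trials, "maybe")


class TestFitFir:
    def test_identical_noise_free_segments_recovered_exactly(self):
        L, n_trials = 12, 4
        template = np.sin(np.linspace(0, np.pi, L))
        data = np.tile(template, n_trials)[None, :]
        norm = st.NormalizedTrialSeries("sub-01", (1,), data, L,
                                        ("yes",) * n_trials, L * TR, TR)
        fir = st.fit_fir(norm)
        assert np.allclose(fir.weights[0], template, atol=1e-12)

    def test_weights_equal_per_lag_trial_mean_oracle(self, rng):
        """On noisy concatenated equal-length trials the FIR least-squares
        solution equals the per-lag across-trial mean to 1e-10."""
        L, n_trials = 9, 3
        data = rng.standard_normal((4, L * n_trials))
        norm = st.NormalizedTrialSeries("sub-01", (1, 2, 3, 4), data, L,
                                        ("no",) * n_trials, L * TR, TR)
        fir = st.fit_fir(norm)
        oracle = data.reshape(4, n_trials, L).mean(axis=1)
        assert np.max(np.abs(fir.weights - oracle)) < 1e-10

    def test_planted_bump_peak_lag_matches_template(self):
        """End-to-end through the generator: the FIR peak lag lies within
        one sample of the convolved planted template's peak."""
        design = synth.StudyDesign(n_subjects=1, n_trials=10,
                                   rt_mean_by_subject=(18.0,), rt_sd=0.0,
                                   rng_seed=0)
        stages = (synth.StageSpec("bump", (1,), 0.2, 0.4),)
        noise = synth.NoiseSpec(white_sd=0.2, ar_coef=0.3, drift_amplitude=0.0)
        ds = synth.synthesize_cohort(design, stages, noise, (1,))
        sid = "sub-01"
        norm = st.normalize_trials(ds.series[sid], ds.trials[sid])
        fir = st.fit_fir(norm)
        noise_free = synth.NoiseSpec(white_sd=0.0, ar_coef=0.0,
                                     drift_amplitude=0.0)
        clean = synth.synthesize_cohort(design, stages, noise_free, (1,))
        clean_norm = st.normalize_trials(clean.series[sid], clean.trials[sid])
        clean_fir = st.fit_fir(clean_norm)
        assert abs(int(fir.weights[0].argmax())
                   - int(clean_fir.weights[0].argmax())) <= 1

    def test_single_trial_rejected(self):
        norm = st.NormalizedTrialSeries("sub-01", (1,), np.zeros((1, 10)), 10,
                                        ("yes",), 10 * TR, TR)
        with pytest.raises(ValueError, match="at least 2"):
            st.fit_fir(norm)


class TestNormalizeResponse:
    def test_length_100_is_identity(self, rng):
        fir = st.FirResponseSet("s", (1,), rng.standard_normal((1, 100)))
        out = st.normalize_response(fir)
        assert np.allclose(out.normalized, fir.weights)

    def test_constant_vector_stays_constant(self):
        fir = st.FirResponseSet("s", (1,), np.full((1, 37), 3.3))
        out = st.normalize_response(fir)
        assert out.normalized.shape == (1, 100)
        assert np.allclose(out.normalized, 3.3)

    def test_peak_fraction_preserved(self):
        """A peak at sample 15 of a 30-sample response maps to the same
        fraction of the 100-point axis within one point."""
        L = 30
        y = np.zeros((1, L))
        y[0, 15] = 1.0
        y[0, 14] = y[0, 16] = 0.5
        out = st.normalize_response(st.FirResponseSet("s", (1,), y))
        peak = int(out.normalized[0].argmax())
        expected = 15 / (L - 1) * 99
        assert abs(peak - expected) <= 1.0


class TestConsensusMap:
    def test_window_grid_has_17_windows(self):
        starts = st.window_grid(20.0, 5.0)
        assert len(starts) == 17
        assert starts[0] == 0.0 and starts[-1] == 80.0

    def test_defaults_match_study_parameters(self):
        import inspect
        sig = inspect.signature(st.consensus_map)
        assert sig.parameters["window_pct"].default == 20.0
        assert sig.parameters["step_pct"].default == 5.0
        assert sig.parameters["top_k"].default == 20
        assert sig.parameters["min_subjects"].default == 8

    @staticmethod
    def _bump_response(peak_idx, n_roi=5, roi=0, amp=1.0):
        resp = np.zeros((n_roi, 100))
        resp[roi, peak_idx - 1] = 0.4 * amp
        resp[roi, peak_idx] = amp
        resp[roi, peak_idx + 1] = 0.4 * amp
        return resp

    def test_unique_bump_binned_for_all_subjects_only_in_covering_windows(self):
        n_subjects = 9
        responses = [st.FirResponseSet(f"s{i}", tuple(range(5)),
                                       np.zeros((5, 30)),
                                       normalized=self._bump_response(30))
                     for i in range(n_subjects)]
        map_ = st.consensus_map(responses, min_subjects=8)
        roi_row = map_.counts[0]
        covering = (map_.window_starts <= 30) & (map_.window_starts + 20 > 30)
        assert np.all(roi_row[covering] == n_subjects)
        assert np.all(roi_row[~covering] == 0)
        assert np.all(map_.counts[1:] == 0)

    def test_top_k_ranking_excludes_weakest_peak(self):
        resp = (self._bump_response(10, roi=0, amp=3.0)
                + self._bump_response(12, roi=1, amp=2.0)
                + self._bump_response(14, roi=2, amp=1.0))
        responses = [st.FirResponseSet("s", tuple(range(5)), np.zeros((5, 30)),
                                       normalized=resp)]
        map_ = st.consensus_map(responses, top_k=2, min_subjects=1)
        window0 = list(map_.counts[:, 0])
        assert window0 == [1, 1, 0, 0, 0]

    def test_bin_bounds_and_per_window_budget(self, rng):
        responses = [st.FirResponseSet(f"s{i}", tuple(range(30)),
                                       np.zeros((30, 40)),
                                       normalized=rng.standard_normal((30, 100)))
                     for i in range(6)]
        map_ = st.consensus_map(responses, top_k=10, min_subjects=4)
        assert map_.counts.max() <= 6
        assert np.all(map_.counts.sum(axis=0) <= 10 * 6)

    def test_label_shuffle_null_rarely_crosses_threshold(self, rng):
        """Independently shuffling each subject's ROI labels destroys
        consensus: above-threshold cells occur in < 1% of cells."""
        design = synth.StudyDesign(n_subjects=10, n_trials=25,
                                   rt_mean_by_subject=tuple(np.linspace(13, 28, 10)),
                                   rng_seed=9)
        stages = (synth.StageSpec("a", (1, 2), 0.0, 0.2),
                  synth.StageSpec("b", (3, 4), 0.4, 0.7))
        noise = synth.NoiseSpec(white_sd=0.8, ar_coef=0.85, drift_amplitude=0.4)
        ds = synth.synthesize_cohort(design, stages, noise,
                                     roi_ids=tuple(range(1, 61)))
        responses = []
        for sid in ds.subject_ids:
            series = prep.detrend_timeseries(ds.series[sid])
            fir = st.normalize_response(st.fit_fir(
                st.normalize_trials(series, ds.trials[sid])))
            shuffled = fir.normalized[rng.permutation(len(fir.roi_ids))]
            responses.append(st.FirResponseSet(sid, fir.roi_ids, fir.weights,
                                               normalized=shuffled))
        map_ = st.consensus_map(responses, min_subjects=8)
        rate = np.mean(map_.thresholded > 0)
        assert rate < 0.01


class TestConditionDifference:
    @staticmethod
    def _map(counts, min_subjects=8, condition="all"):
        counts = np.asarray(counts)
        return st.SpatiotemporalMap(tuple(range(counts.shape[0])), counts,
                                    st.window_grid(), 20.0, 5.0, 20,
                                    min_subjects, 14, condition)

    def test_identical_maps_give_empty_difference(self):
        counts = np.random.default_rng(0).integers(0, 14, (4, 17))
        diff = st.condition_difference(self._map(counts), self._map(counts))
        assert not diff.retained.any()

    def test_large_cell_difference_retained_with_yes_dominance(self):
        yes = np.zeros((2, 17), dtype=int)
        no = np.zeros((2, 17), dtype=int)
        yes[0, 3], no[0, 3] = 14, 3
        diff = st.condition_difference(self._map(yes), self._map(no), min_diff=7)
        assert diff.retained[0, 3]
        frame = diff.to_frame()
        assert frame.iloc[0]["dominant"] == "yes"
        assert frame.iloc[0]["n_yes_minus_n_no"] == 11

    def test_grid_mismatch_rejected(self):
        a = self._map(np.zeros((2, 17), dtype=int))
        b = st.SpatiotemporalMap((0, 1), np.zeros((2, 9), dtype=int),
                                 st.window_grid(20, 10), 20.0, 10.0, 20, 8, 14)
        with pytest.raises(ValueError, match="grids"):
            st.condition_difference(a, b)

    def test_yes_only_late_stage_yields_yes_dominant_late_cells(self):
        """Generator-planted condition effect: a late yes-only stage shows
        up as yes-dominant retained cells in late windows."""
        design = synth.StudyDesign(n_subjects=14, n_trials=25,
                                   rt_mean_by_subject=tuple(np.linspace(16, 30, 14)),
                                   rng_seed=4)
        stages = (synth.StageSpec("late-yes", (1, 2), 0.55, 0.85, 1.2, 0.0),)
        noise = synth.NoiseSpec(white_sd=0.8, ar_coef=0.85, drift_amplitude=0.4)
        ds = synth.synthesize_cohort(design, stages, noise,
                                     roi_ids=tuple(range(1, 61)))
        maps = {}
        for condition in ("yes", "no"):
            responses = []
            for sid in ds.subject_ids:
                series = prep.detrend_timeseries(ds.series[sid])
                responses.append(st.normalize_response(st.fit_fir(
                    st.normalize_trials(series, ds.trials[sid], condition))))
            maps[condition] = st.consensus_map(responses, condition=condition)
        diff = st.condition_difference(maps["yes"], maps["no"], min_diff=7)
        frame = diff.to_frame()
        stage_cells = frame[frame["roi_id"].isin([1, 2])]
        assert not stage_cells.empty
        assert (stage_cells["dominant"] == "yes").all()
        assert stage_cells["window_start_pct"].min() >= 50


class TestOrderRecoveryHelpers:
    def test_rotation_predicate(self):
        assert st.is_rotation([2, 0, 1], [0, 1, 2])
        assert st.is_rotation([0, 1, 2], [0, 1, 2])
        assert not st.is_rotation([1, 0, 2], [0, 1, 2])

    def test_earliest_window_none_when_below_threshold(self):
        map_ = TestConditionDifference._map(np.zeros((3, 17), dtype=int))
        assert st.earliest_window(map_, [0, 1]) is None
        assert st.stage_order(map_, [[0], [1], [2]]) is None
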