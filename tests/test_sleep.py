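"""Sleep scoring: the five-minute rule, bouts, profiles, rebound."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from behavkit.core import BehavTable
from behavkit.sleep import (
    SleepParams,
    bout_analysis,
    bouts_to_series,
    classify_movement,
    heatmap_matrix,
    rebound_quantification,
    sleep_annotation,
    sleep_profile,
)

P = SleepParams()


def _series(moving, sid="a", bin_s=10.0, t0=0.0):
    return pd.DataFrame({
        "id": sid,
        "t": t0 + bin_s * np.arange(len(moving)),
        "moving": [float(m) if m is not None else np.nan for m in moving],
    })


class TestSleepParams:
    def test_min_sleep_must_be_bin_multiple(self):
        with pytest.raises(ValueError):
            SleepParams(bin_s=10.0, min_sleep_s=305.0)

    def test_defaults_encode_the_five_minute_rule(self):
        assert P.min_sleep_s == 300.0
        assert P.bin_s == 10.0


class TestClassifyMovement:
    def _bt(self, disp, frame_s=1.0):
        data = pd.DataFrame({"id": "a",
                             "t": frame_s * np.arange(len(disp)),
                             "displacement": disp})
        return BehavTable(data, pd.DataFrame({"id": ["a"]}))

    def test_all_still_is_all_inactive(self):
        ms = classify_movement(self._bt([0.0] * 40), P)
        assert (ms["moving"] == 0).all()

    def test_single_fast_frame_marks_whole_bin_moving(self):
        disp = [0.0] * 40
        disp[13] = 5.0   # one frame above threshold inside bin [10, 20)
        ms = classify_movement(self._bt(disp), P)
        assert ms.loc[ms["t"] == 10.0, "moving"].iloc[0] == 1.0
        assert ms.loc[ms["t"] != 10.0, "moving"].eq(0).all()

    def test_infinite_threshold_means_never_moving(self):
        params = SleepParams(velocity_threshold=np.inf)
        ms = classify_movement(self._bt([100.0] * 40), params)
        assert (ms["moving"] == 0).all()

    def test_gap_bins_are_missing_not_zero(self):
        data = pd.DataFrame({"id": "a", "t": [0.0, 5.0, 35.0],
                             "displacement": [2.0, 2.0, 2.0]})
        bt = BehavTable(data, pd.DataFrame({"id": ["a"]}))
        ms = classify_movement(bt, P)
        assert np.isnan(ms.loc[ms["t"] == 10.0, "moving"]).all()
        assert np.isnan(ms.loc[ms["t"] == 20.0, "moving"]).all()


class TestSleepAnnotation:
    def test_exactly_five_minutes_is_sleep(self):
        ms = _series([1] + [0] * 30 + [1])
        ann = sleep_annotation(ms, P)
        assert ann["asleep"].sum() == 30     # the full 300-s run

    def test_290_seconds_is_not_sleep(self):
        ms = _series([1] + [0] * 29 + [1])
        ann = sleep_annotation(ms, P)
        assert ann["asleep"].sum() == 0

    def test_fully_active_series_has_zero_sleep(self):
        ann = sleep_annotation(_series([1] * 60), P)
        assert ann["asleep"].sum() == 0

    def test_missing_bin_breaks_the_run(self):
        # two 150-s inactive runs separated by one missing bin: no sleep
        ms = _series([0] * 15 + [None] + [0] * 15)
        ann = sleep_annotation(ms, P)
        assert ann["asleep"].fillna(0).sum() == 0

    def test_never_asleep_while_moving(self, hmm_sim):
        params = SleepParams(bin_s=60.0, min_sleep_s=300.0)
        ms = classify_movement(hmm_sim.behav, params)
        ann = sleep_annotation(ms, params)
        both = (ann["asleep"] == 1) & (ann["moving"] == 1)
        assert not both.any()

    def test_idempotent(self):
        ms = _series([1, 0, 0, 1] + [0] * 35 + [1])
        once = sleep_annotation(ms, P)
        twice = sleep_annotation(once, P)
        pd.testing.assert_series_equal(once["asleep"], twice["asleep"])

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=120),
           st.integers(1, 6))
    def test_lowering_threshold_never_decreases_sleep(self, moving, k):
        ms = _series(moving)
        lo = SleepParams(min_sleep_s=10.0 * k)
        hi = SleepParams(min_sleep_s=10.0 * (k + 2))
        s_lo = sleep_annotation(ms, lo)["asleep"].sum()
        s_hi = sleep_annotation(ms, hi)["asleep"].sum()
        assert s_lo >= s_hi


class TestBoutAnalysis:
    def test_run_length_encoding(self):
        ms = _series([0, 0, 1, 1, 1, 0])
        bouts = bout_analysis(ms, "moving", bin_s=10.0)
        assert [(b.state, b.duration_s) for b in bouts.itertuples()] == [
            (0.0, 20.0), (1.0, 30.0), (0.0, 10.0)]

    def test_single_bin_bout(self):
        bouts = bout_analysis(_series([1]), "moving", bin_s=10.0)
        assert len(bouts) == 1 and bouts["duration_s"].iloc[0] == 10.0

    def test_durations_cover_span(self):
        ms = _series([0, 1, 1, 0, 0, 0, 1])
        bouts = bout_analysis(ms, "moving", bin_s=10.0)
        assert bouts["duration_s"].sum() == 70.0

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=80))
    def test_encode_decode_is_identity(self, labels):
        ms = _series(labels)
        bouts = bout_analysis(ms, "moving", bin_s=10.0)
        back = bouts_to_series(bouts, bin_s=10.0)
        np.testing.assert_array_equal(back["state"].to_numpy(),
                                      ms["moving"].to_numpy())
        np.testing.assert_allclose(back["t"].to_numpy(), ms["t"].to_numpy())


class TestSleepProfile:
    def _annotated(self, asleep_by_id):
        frames = [pd.DataFrame({
            "id": sid,
            "t": 1800.0 * np.arange(len(v)),
            "moving": 0.0,
            "asleep": v,
        }) for sid, v in asleep_by_id.items()]
        return pd.concat(frames, ignore_index=True)

    def test_unanimous_sleep_gives_degenerate_ci(self):
        ann = self._annotated({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        meta = pd.DataFrame({"id": ["a", "b"]})
        prof = sleep_profile(ann, meta, seed=0)
        assert (prof["mean_fraction_asleep"] == 1.0).all()
        assert (prof["ci_low"] == 1.0).all() and (prof["ci_high"] == 1.0).all()

    def test_single_specimen_ci_collapses_to_point(self):
        ann = self._annotated({"a": [1.0, 0.0]})
        prof = sleep_profile(ann, pd.DataFrame({"id": ["a"]}), seed=0)
        assert (prof["ci_low"] == prof["mean_fraction_asleep"]).all()

    def test_two_opposite_specimens(self):
        # resamples of {0, 1} can only produce means 0, 0.5 or 1
        ann = self._annotated({"a": [0.0], "b": [1.0]})
        meta = pd.DataFrame({"id": ["a", "b"]})
        prof = sleep_profile(ann, meta, n_boot=400, seed=1)
        assert prof["mean_fraction_asleep"].iloc[0] == pytest.approx(0.5)
        assert set(prof[["ci_low", "ci_high"]].iloc[0]) <= {0.0, 0.5, 1.0}

    def test_groups_without_specimens_omitted(self):
        ann = self._annotated({"a": [1.0]})
        meta = pd.DataFrame({"id": ["a", "ghost"],
                             "genotype": ["x", "y"]})
        prof = sleep_profile(ann, meta, group_by="genotype", seed=0)
        assert set(prof["group"]) == {"x"}


class TestHeatmapMatrix:
    def test_shape_and_meta_row_order(self, small_behav):
        mat = heatmap_matrix(small_behav.data, small_behav.meta,
                             "displacement", bin_s=900.0)
        assert list(mat.index) == list(small_behav.meta["id"])
        assert mat.shape == (4, 4)          # 3600 s / 900 s bins
        assert mat.loc["d"].isna().all()    # registered, never recorded

    def test_column_means_equal_population_profile(self, small_behav):
        # binning by mean per specimen then averaging = population mean
        mat = heatmap_matrix(small_behav.data, small_behav.meta,
                             "displacement", bin_s=900.0)
        binned = small_behav.bin_time("displacement", 900.0, "mean")
        pop = binned.groupby("t_bin")["displacement"].mean()
        np.testing.assert_allclose(mat.mean(axis=0).to_numpy(),
                                   pop.to_numpy())

    def test_constant_input_constant_matrix(self):
        data = pd.DataFrame({"id": "a", "t": 10.0 * np.arange(360),
                             "v": 2.0})
        meta = pd.DataFrame({"id": ["a"]})
        mat = heatmap_matrix(data, meta, "v", bin_s=900.0)
        assert (mat.to_numpy() == 2.0).all()


class TestRebound:
    def _annotated(self, asleep_by_id, bin_s=60.0):
        frames = [pd.DataFrame({
            "id": sid, "t": bin_s * np.arange(len(v)), "asleep": v,
        }) for sid, v in asleep_by_id.items()]
        return pd.concat(frames, ignore_index=True)

    def test_identical_windows_give_zero_delta(self):
        ann = self._annotated({"a": [1.0, 0.0, 1.0, 0.0]})
        per, summary, excl = rebound_quantification(
            ann, pd.DataFrame({"id": ["a"]}),
            baseline_window=(0.0, 240.0), rebound_window=(0.0, 240.0),
            bin_s=60.0, seed=0)
        assert per["delta_min"].iloc[0] == 0.0

    def test_delta_in_minutes(self):
        ann = self._annotated({"a": [0.0] * 60 + [1.0] * 60})
        per, _, _ = rebound_quantification(
            ann, pd.DataFrame({"id": ["a"]}),
            baseline_window=(0.0, 3600.0), rebound_window=(3600.0, 7200.0),
            bin_s=60.0, seed=0)
        assert per["delta_min"].iloc[0] == pytest.approx(60.0)

    def test_specimen_missing_a_window_excluded_and_reported(self):
        ann = self._annotated({"a": [1.0] * 120, "b": [1.0] * 30})
        per, _, excl = rebound_quantification(
            ann, pd.DataFrame({"id": ["a", "b"]}),
            baseline_window=(0.0, 3600.0), rebound_window=(3600.0, 7200.0),
            bin_s=60.0, seed=0)
        assert excl == ["b"]
        assert list(per["id"]) == ["a"]

    def test_mismatched_window_spans_rejected(self):
        ann = self._annotated({"a": [1.0] * 10})
        with pytest.raises(ValueError, match="equal span"):
            rebound_quantification(ann, pd.DataFrame({"id": ["a"]}),
                                   (0.0, 600.0), (600.0, 900.0), seed=0)

    def test_deprived_cohort_shows_positive_rebound(self):
        # simulator with a deprivation night and post-deprivation
        # sleep-pressure boost: rebound window sleeps more than baseline
        from behavkit.simulate import Genotype, SimConfig, simulate_population
        from behavkit.sleep import classify_movement, sleep_annotation
        day = 86400.0
        cfg = SimConfig(genotypes=[Genotype("w", 24.0, 8)], days=3.0,
                        bin_s=60.0, seed=9,
                        deprivation_windows=[(1.5 * day, 2.0 * day)])
        sim = simulate_population(cfg)
        params = SleepParams(bin_s=60.0, min_sleep_s=300.0)
        ann = sleep_annotation(classify_movement(sim.behav, params), params)
        per, summary, _ = rebound_quantification(
            ann, sim.behav.meta,
            baseline_window=(1.0 * day, 1.5 * day),      # baseline night+day
            rebound_window=(2.0 * day, 2.5 * day),       # post-deprivation
            bin_s=60.0, seed=2)
        assert summary["mean_delta_min"].iloc[0] > 0
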