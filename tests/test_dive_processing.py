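import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirounga import dive_processing as dp
from mirounga import synthetic_data as sd
from conftest import make_series


class TestSubsample:
    def test_eight_second_input_is_identity(self):
        s = make_series(np.arange(100), dt=8.0)
        out = dp.subsample_depth(s, 8.0)
        pd.testing.assert_frame_equal(out, s)

    def test_one_second_input_thinned_eightfold(self):
        s = make_series(np.arange(800), dt=1.0)
        assert len(dp.subsample_depth(s, 8.0)) == 100

    def test_kept_samples_equal_source_at_kept_indices(self):
        t = np.arange(0, 400, 2.0)
        s = pd.DataFrame({"time_s": t, "depth_m": np.sin(t / 30.0) * 50 + 60})
        out = dp.subsample_depth(s, 8.0)
        assert np.array_equal(out["depth_m"].to_numpy(), s["depth_m"].to_numpy()[::4])
        assert np.array_equal(out["time_s"].to_numpy(), s["time_s"].to_numpy()[::4])

    def test_non_divisor_interval_rejected(self):
        s = make_series(np.zeros(100), dt=3.0)
        with pytest.raises(ValueError, match="divide"):
            dp.subsample_depth(s, 8.0)


class TestDetectDives:
    def test_flat_surface_record_has_no_dives(self):
        assert dp.detect_dives(make_series(np.zeros(500))) == []

    def test_v_excursion_to_20m_60s_is_one_dive(self):
        prof = np.concatenate([np.zeros(10), [5, 12, 20, 20, 20, 12, 5], np.zeros(10)])
        segs = dp.detect_dives(make_series(prof, dt=10.0))
        assert len(segs) == 1
        assert segs[0]["duration_min"] * 60 > 32

    def test_each_threshold_rejects_on_its_own(self):
        # 20 m but only ~24 s; then 10 m for 300 s: both rejected
        shallow_long = [10.0] * 38  # 304 s at 10 m
        deep_short = [20.0] * 3  # 24 s at 20 m
        prof = np.concatenate([np.zeros(5), deep_short, np.zeros(5), shallow_long, np.zeros(5)])
        assert dp.detect_dives(make_series(prof, dt=8.0)) == []

    def test_post_dive_interval_is_time_to_next_dive(self):
        dive = [0, 30, 30, 30, 30, 0]
        prof = np.concatenate([dive, np.zeros(10), dive])
        segs = dp.detect_dives(make_series(prof, dt=16.0))
        assert len(segs) == 2
        gap_s = segs[1]["start_s"] - segs[0]["end_s"]
        assert segs[0]["post_dive_interval_min"] == pytest.approx(gap_s / 60.0)
        assert np.isnan(segs[1]["post_dive_interval_min"])


class TestDiveMetrics:
    def _metrics(self, prof, dt=8.0):
        s = make_series(prof, dt=dt)
        segs = dp.detect_dives(s)
        assert len(segs) == 1
        return dp.dive_metrics(s, segs[0])

    def test_square_wave_efficiency_half(self):
        # 10 min at 100 m, then 10 min at 30 m (below the 80% band): 20 min
        # submerged, bottom time 10 -> efficiency 0.5
        prof = np.concatenate([np.zeros(3), [100.0] * 75, [30.0] * 75, np.zeros(3)])
        m = self._metrics(prof)
        assert m["bottom_time_min"] == pytest.approx(10.0, abs=0.3)
        assert m["efficiency"] == pytest.approx(0.5, abs=0.03)

    def test_three_reversals_of_6m_counted(self):
        bottom = [100, 94, 100, 94, 100, 94, 100]
        prof = np.concatenate([np.zeros(2), [50.0], bottom, [50.0], np.zeros(2)])
        m = self._metrics(prof)
        assert m["n_excursions"] == 3

    def test_sharp_v_dive_has_near_zero_efficiency(self):
        prof = np.concatenate([np.zeros(2), [6, 12, 18, 24, 18, 12, 6], np.zeros(2)])
        m = self._metrics(prof)
        assert m["bottom_time_min"] <= 8.0 / 60.0 + 1e-9
        assert m["efficiency"] < 0.05

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=800.0), min_size=10, max_size=300))
    def test_efficiency_bounds_hold_for_arbitrary_profiles(self, depths):
        s = make_series(np.array(depths), dt=8.0)
        for seg in dp.detect_dives(s):
            m = dp.dive_metrics(s, seg)
            assert 0.0 <= m["efficiency"] <= 1.0
            assert 0.0 <= m["bottom_time_min"] <= m["duration_min"]
            assert m["n_excursions"] >= 0


class TestClassifyDive:
    def _classify(self, prof, seafloor=None, dt=8.0):
        s = make_series(prof, dt=dt)
        segs = dp.detect_dives(s)
        rec = dp.dive_metrics(s, segs[0])
        return dp.classify_dive(s, rec, seafloor)

    def test_wiggle_free_v_dive_is_transit(self):
        prof = np.concatenate([np.zeros(2), np.linspace(0, 300, 20), np.linspace(300, 0, 20), np.zeros(2)])
        assert self._classify(prof) == "transit"

    def test_flat_bottom_at_248_over_250m_seafloor_is_benthic(self):
        bottom = 248.0 + 4.0 * np.sin(np.linspace(0, 6 * np.pi, 60))
        prof = np.concatenate([np.zeros(2), np.linspace(0, 248, 15), bottom, np.linspace(248, 0, 15), np.zeros(2)])
        assert self._classify(prof, seafloor=250.0) == "benthic_foraging"

    def test_wiggly_550m_dive_over_deep_seafloor_is_pelagic(self):
        bottom = 550.0 - 8.0 * np.abs(np.sin(np.linspace(0, 6 * np.pi, 90)))
        prof = np.concatenate([np.zeros(2), np.linspace(0, 550, 25), bottom, np.linspace(550, 0, 25), np.zeros(2)])
        assert self._classify(prof, seafloor=3000.0) == "pelagic_foraging"

    def test_slow_monotone_segment_is_drift(self):
        # descend to 150 m, drift down at 0.15 m/s for 12 min, ascend
        drift = 150.0 + 0.15 * 8.0 * np.arange(90)
        prof = np.concatenate([np.zeros(2), np.linspace(0, 150, 12), drift, np.linspace(drift[-1], 0, 20), np.zeros(2)])
        assert self._classify(prof) == "drift"

    def test_missing_seafloor_skips_benthic_rule(self):
        bottom = 248.0 + 4.0 * np.sin(np.linspace(0, 6 * np.pi, 60))
        prof = np.concatenate([np.zeros(2), np.linspace(0, 248, 15), bottom, np.linspace(248, 0, 15), np.zeros(2)])
        assert self._classify(prof, seafloor=None) == "pelagic_foraging"


class TestDielAndGeoreference:
    def test_equator_noon_day_midnight_night(self):
        assert dp.assign_diel("2015-03-20T12:00:00", 0.0, 0.0) == "day"
        assert dp.assign_diel("2015-03-20T00:00:00", 0.0, 0.0) == "night"

    def test_missing_position_raises(self):
        with pytest.raises(ValueError, match="georeferenced"):
            dp.assign_diel("2015-03-20T12:00:00", np.nan, 0.0)

    def _hourly(self):
        return pd.DataFrame(
            {
                "timestamp": pd.date_range("2010-01-01", periods=5, freq="h"),
                "lat": [37.0, 37.1, 37.2, 37.3, 37.4],
                "lon": [-122.0, -122.1, -122.2, -122.3, -122.4],
            }
        )

    def test_dive_on_hourly_timestamp_gets_that_position(self):
        dives = pd.DataFrame({"mid_timestamp": [np.datetime64("2010-01-01T02:00:00")]})
        out = dp.georeference_dives(dives, self._hourly())
        assert out["lat"].iloc[0] == pytest.approx(37.2)
        assert not out["unplaced"].iloc[0]

    def test_halfway_dive_gets_midpoint(self):
        dives = pd.DataFrame({"mid_timestamp": [np.datetime64("2010-01-01T02:30:00")]})
        out = dp.georeference_dives(dives, self._hourly())
        assert out["lat"].iloc[0] == pytest.approx(37.25)
        assert out["lon"].iloc[0] == pytest.approx(-122.25)

    def test_outside_span_flagged_unplaced(self):
        dives = pd.DataFrame({"mid_timestamp": [np.datetime64("2010-01-02T00:00:00")]})
        out = dp.georeference_dives(dives, self._hourly())
        assert out["unplaced"].iloc[0]
        assert np.isnan(out["lat"].iloc[0])

    def test_interpolated_positions_stay_in_bracketing_box(self):
        rng = np.random.default_rng(0)
        h = self._hourly()
        mids = h["timestamp"].iloc[0] + pd.to_timedelta(rng.uniform(0, 4 * 3600, 50), unit="s")
        out = dp.georeference_dives(pd.DataFrame({"mid_timestamp": mids}), h)
        assert out["lat"].between(h["lat"].min(), h["lat"].max()).all()
        assert out["lon"].between(h["lon"].min(), h["lon"].max()).all()


class TestZeroOffset:
    def test_surface_drift_removed_before_detection(self):
        # a 3 m sensor offset would fake shallow "dives" and shift depths
        rng = np.random.default_rng(1)
        series, truth = sd.simulate_dive_series({"transit": 1.0}, duration_h=2, seed=4)
        drifted = series.copy()
        drifted["depth_m"] = drifted["depth_m"] + 3.0
        corrected = dp.zero_offset_correct(drifted)
        segs = dp.detect_dives(corrected)
        assert len(segs) == len(truth)


def test_type_proportions_sum_to_one_per_deployment(processed):
    for did, dives in processed["dives"].items():
        props = dives["dive_type"].value_counts(normalize=True)
        assert props.sum() == pytest.approx(1.0, abs=1e-9)


def test_recovery_above_chance_and_monotone_in_noise():
    """Type recovery is perfect without noise and degrades gracefully."""
    accs = []
    for noise in (0.0, 1.0, 6.0):
        cfg = sd.scaled_config(seed=13, trip_days=3.0, n_per_strategy={"male": 1, "female_pb": 1, "female_pm": 0})
        cfg.depth_noise_sd_m = noise
        coh = sd.simulate_cohort(cfg)
        hits = tot = 0
        for dep in coh.deployments:
            hourly = coh.true_paths[dep.deployment_id]
            dives = dp.process_deployment(
                coh.dive_series[dep.deployment_id],
                hourly=hourly,
                seafloor_fn=cfg.geometry.seafloor_depth_m,
            )
            tr = coh.dive_truth[dep.deployment_id]
            m = min(len(dives), len(tr))
            hits += (dives["dive_type"].to_numpy()[:m] == tr["dive_type"].to_numpy()[:m]).sum()
            tot += m
        accs.append(hits / tot)
    assert accs[0] == 1.0
    assert accs[0] >= accs[1] >= accs[2] - 1e-9
    assert accs[2] > 0.5  # well above the 1-in-4 chance level
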