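"""Argos track cleaning: duplicates, speed/angle filter, trips, move persistence."""

import numpy as np
import pandas as pd
import pytest

import divestates as ds
from divestates.errors import InputError
from divestates.tracks import haversine_km


def frame(times, lons, lats, lc="3", ind="a", g=None):
    df = pd.DataFrame(
        {
            "id": ind,
            "time": np.asarray(times, float),
            "lon": np.asarray(lons, float),
            "lat": np.asarray(lats, float),
            "lc": lc if isinstance(lc, list) else [lc] * len(times),
        }
    )
    if g is not None:
        df["g"] = g
    return df


class TestNearDuplicates:
    def test_fix_90s_after_previous_is_dropped(self):
        out = ds.remove_near_duplicates(frame([0, 90], [0, 0], [0, 0]))
        assert list(out["time"]) == [0.0]

    def test_fix_121s_after_previous_is_kept(self):
        out = ds.remove_near_duplicates(frame([0, 121], [0, 0], [0, 0]))
        assert list(out["time"]) == [0.0, 121.0]

    def test_empty_input(self):
        out = ds.remove_near_duplicates(frame([], [], []))
        assert out.empty

    def test_window_measured_from_retained_fix(self):
        # 0, 100, 200: 100 dropped, 200 kept (200 - 0 > 120)
        out = ds.remove_near_duplicates(frame([0, 100, 200], [0] * 3, [0] * 3))
        assert list(out["time"]) == [0.0, 200.0]

    def test_unsorted_input_rejected(self):
        with pytest.raises(InputError):
            ds.remove_near_duplicates(frame([100, 0], [0, 0], [0, 0]))


class TestSdaFilter:
    def test_class_z_removed_regardless_of_geometry(self):
        df = frame([0, 3600, 7200, 10800], [0, 0.01, 0.02, 0.03], [0] * 4,
                   lc=["3", "Z", "3", "3"])
        out = ds.sda_filter(df)
        assert "Z" not in set(out["lc"])

    def test_speed_violation_removes_out_of_sequence_fix(self):
        # slow eastward track with one fix 10 km north: > 5 km/h both ways
        lats = [0.0, 0.0, 10.0 / 111.32, 0.0, 0.0]
        lons = [0.0, 0.01, 0.02, 0.03, 0.04]
        df = frame(np.arange(5) * 3600.0, lons, lats)
        v = haversine_km(lons[1], lats[1], lons[2], lats[2])  # sanity: ~10 km in 1 h
        assert v > 5.0
        out = ds.sda_filter(df)
        assert len(out) == 4
        assert out["lat"].max() < 0.05

    def test_collinear_slow_track_unchanged(self):
        df = frame(np.arange(10) * 3600.0, np.arange(10) * 0.018, [0.0] * 10)
        out = ds.sda_filter(df)
        assert len(out) == 10

    def test_output_is_subsequence_and_keeps_endpoints(self):
        tr = ds.simulate_argos_track(9, 200, outlier_rate=0.1)
        out = ds.sda_filter(tr)
        merged = pd.merge(out, tr, on=["time", "lon", "lat"], how="left")
        assert len(merged) == len(out)  # every output fix is an input fix
        assert out["time"].iloc[0] == tr["time"].iloc[0]
        assert out["time"].iloc[-1] == tr["time"].iloc[-1]

    def test_under_three_fixes_returned_with_warning(self):
        df = frame([0, 3600], [0, 50], [0, 50])  # absurd speed, but too few fixes
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = ds.sda_filter(df)
        assert len(out) == 2


class TestTrips:
    def test_eight_day_gap_splits_into_two_trips(self):
        t = np.concatenate([np.arange(5) * 3600.0, 8 * 86400 + np.arange(5) * 3600.0])
        trips = ds.split_trips(frame(t, [0] * 10, [0] * 10))
        assert len(trips) == 2

    def test_exactly_seven_day_gap_is_one_trip(self):
        t = np.array([0.0, 7 * 86400.0])
        trips = ds.split_trips(frame(t, [0, 0], [0, 0]))
        assert len(trips) == 1

    def test_no_gaps_is_one_trip(self):
        trips = ds.split_trips(frame(np.arange(10) * 7200.0, [0] * 10, [0] * 10))
        assert len(trips) == 1


class TestMovePersistence:
    def test_median_split_two_values(self):
        df = frame([0, 1], [0, 0], [0, 0], g=[0.2, 0.8])
        out = ds.classify_move_persistence(df)
        assert list(out["mp_class"]) == ["localised", "transiting"]

    def test_all_equal_g_all_transiting(self):
        df = frame([0, 1, 2], [0] * 3, [0] * 3, g=[0.5, 0.5, 0.5])
        out = ds.classify_move_persistence(df)
        assert set(out["mp_class"]) == {"transiting"}

    def test_individuals_classified_independently(self):
        rng = np.random.default_rng(0)
        a = frame(np.arange(400.0), [0] * 400, [0] * 400, ind="a",
                  g=rng.uniform(0.0, 0.4, 400))
        b = frame(np.arange(400.0), [0] * 400, [0] * 400, ind="b",
                  g=rng.uniform(0.6, 1.0, 400))
        out = ds.classify_move_persistence(pd.concat([a, b], ignore_index=True))
        for ind in ("a", "b"):
            prop = (out[out["id"] == ind]["mp_class"] == "localised").mean()
            assert prop == pytest.approx(0.5, abs=0.01)

    def test_transiting_proportion_at_least_half(self):
        rng = np.random.default_rng(4)
        df = frame(np.arange(101.0), [0] * 101, [0] * 101, g=rng.uniform(0, 1, 101))
        out = ds.classify_move_persistence(df)
        assert (out["mp_class"] == "transiting").mean() >= 0.5

    def test_missing_g_rejected(self):
        with pytest.raises(InputError):
            ds.classify_move_persistence(frame([0], [0], [0]))


class TestLinkDives:
    def dives(self, starts):
        return pd.DataFrame({"dive_id": range(len(starts)), "start_time": starts})

    def track(self):
        return pd.DataFrame(
            {
                "time": [43800.0, 51000.0],  # 12:10 dive joins the 12:00 fix
                "lon": [1.0, 2.0],
                "lat": [10.0, 20.0],
            }
        )

    def test_joins_nearest_fix(self):
        track = pd.DataFrame({"time": [43200.0, 50400.0], "lon": [1.0, 2.0], "lat": [10.0, 20.0]})
        out = ds.link_dives_to_track(self.dives([43800.0]), track)
        assert out.loc[0, "lon"] == 1.0

    def test_beyond_tolerance_gives_null(self):
        track = pd.DataFrame({"time": [0.0], "lon": [1.0], "lat": [10.0]})
        out = ds.link_dives_to_track(self.dives([5400.0]), track)  # 90 min away
        assert np.isnan(out.loc[0, "lon"])

    def test_join_order_independent(self):
        rng = np.random.default_rng(1)
        starts = rng.uniform(0, 1e5, 50)
        track = pd.DataFrame(
            {"time": np.arange(0, 1.2e5, 7200.0), "lon": rng.normal(size=17),
             "lat": rng.normal(size=17)}
        )
        a = ds.link_dives_to_track(self.dives(starts), track)
        b = ds.link_dives_to_track(self.dives(starts[::-1]), track)
        merged = a.merge(b, on="start_time", suffixes=("_a", "_b"))
        assert np.allclose(merged["lon_a"], merged["lon_b"], equal_nan=True)
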