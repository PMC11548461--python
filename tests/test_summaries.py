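import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

import herdhmm as hh
from herdhmm import summaries


def _decoded_frame(n=96, state="resting", start="2022-01-10"):
    ts = pd.date_range(start, periods=n, freq="30min")
    return pd.DataFrame(
        {
            "animal_id": "A00",
            "herd_id": "H00",
            "herd_type": "resident",
            "timestamp": ts,
            "state": state,
            "diel": ["day" if 8 <= t.hour < 18 else "night" for t in ts],
            "season": "cold_dry",
            "step_m": 0.0,
        }
    )


class TestActivityBudget:
    def test_single_state_proportion_one(self):
        out = summaries.activity_budget(_decoded_frame(), keys=("hour",))
        assert np.allclose(out["p_resting"], 1.0)

    def test_proportions_sum_to_one_and_counts_conserve(self):
        rng = np.random.default_rng(0)
        df = _decoded_frame(500)
        df["state"] = rng.choice(["resting", "foraging", "travelling"], 500)
        out = summaries.activity_budget(df, keys=("hour", "diel"))
        probs = out[[c for c in out.columns if c.startswith("p_")]].sum(axis=1)
        assert np.allclose(probs, 1.0, atol=1e-12)
        assert out["total"].sum() == len(df)

    def test_missing_key_rejected(self):
        with pytest.raises(ValueError):
            summaries.activity_budget(_decoded_frame(), keys=("unit",))

    def test_resident_night_resting_share(self, small_survey, ref_model):
        truth = small_survey.truth
        df = pd.DataFrame(
            {
                "animal_id": truth["animal_id"],
                "herd_id": "H",
                "herd_type": ["transhumant" if a == "A00" else "resident"
                              for a in truth["animal_id"]],
                "timestamp": pd.to_datetime(truth["timestamp_utc"]),
                "state": [("resting", "foraging", "travelling")[s]
                          for s in truth["true_state"]],
            }
        )
        labels = hh.label_time(df["timestamp"],
                               (small_survey.config.home_lat,
                                small_survey.config.home_lon))
        df["diel"] = labels["diel"].to_numpy()
        out = summaries.activity_budget(df, keys=("herd_type", "diel"))
        row = out[(out["herd_type"] == "resident") & (out["diel"] == "night")]
        # tether covers the night except a one-hour margin at each edge
        assert float(row["p_resting"].iloc[0]) >= 0.80


class TestDailyMetrics:
    def test_full_resting_day(self):
        df = _decoded_frame()
        out = summaries.daily_metrics(df, daytime_only=True)
        assert len(out) == 2  # the range spans midnight into a second day
        day = out.iloc[0]
        assert day["d_resting_m"] == 0.0
        assert day["t_resting_h"] == 0.5 * (df["diel"] == "day").sum() / 2

    def test_state_times_conserve_observation_span(self):
        rng = np.random.default_rng(1)
        df = _decoded_frame(48 * 2)
        df["state"] = rng.choice(["resting", "foraging"], len(df))
        df["step_m"] = rng.uniform(0, 700, len(df))
        out = summaries.daily_metrics(df, daytime_only=False)
        t_cols = [c for c in out.columns if c.startswith("t_")]
        assert np.allclose(out[t_cols].sum(axis=1), 0.5 * out["n_fixes"])

    def test_distance_sums_steps_by_state(self):
        df = _decoded_frame(8)
        df["diel"] = "day"
        df["state"] = ["resting"] * 4 + ["foraging"] * 4
        df["step_m"] = np.arange(8.0)
        out = summaries.daily_metrics(df, daytime_only=True)
        assert out["d_resting_m"].iloc[0] == pytest.approx(0 + 1 + 2 + 3)
        assert out["d_foraging_m"].iloc[0] == pytest.approx(4 + 5 + 6 + 7)


class TestClusterDurations:
    def test_three_cluster_oracle(self):
        durations = [10, 11, 12, 28, 30, 32, 70, 80]
        means, labels = summaries.cluster_durations(durations, 3, seed=0)
        assert means == pytest.approx([11.0, 30.0, 75.0])
        assert labels == [0, 0, 0, 1, 1, 1, 2, 2]

    def test_deterministic_given_seed(self):
        durations = [3, 9, 12, 40, 41, 70]
        a = summaries.cluster_durations(durations, 3, seed=5)
        b = summaries.cluster_durations(durations, 3, seed=5)
        assert a == b


def _journey_track(seed=0):
    """A hand-built daily-resolution journey: home, out, two stops, back."""
    rng = np.random.default_rng(seed)
    rows = []
    day = dt.date(2022, 3, 1)
    # (days, centre offset km east)
    plan = [(10, 0.0), (2, 8.0), (12, 20.0), (2, 35.0), (30, 50.0), (2, 20.0),
            (8, 0.0)]
    for n_days, east in plan:
        for _ in range(n_days):
            for h in range(0, 24, 2):
                rows.append(
                    {
                        "timestamp": dt.datetime.combine(day, dt.time(h)),
                        "lat": 14.5 + rng.normal(0, 1e-3),
                        "lon": -16.5 + east / 107.0 + rng.normal(0, 1e-3),
                    }
                )
            day += dt.timedelta(days=1)
    return pd.DataFrame(rows)


class TestDetectStopsAndPhases:
    def test_journey_segmentation(self):
        track = _journey_track()
        home = Point(-16.5, 14.5).buffer(0.03)
        rec = summaries.detect_stops_and_phases(track, home,
                                                summaries.StopParams(),
                                                herd_id="H00")
        assert rec.departure == dt.date(2022, 3, 11)
        # first day back inside home: 10+2+12+2+30+2 days after the start
        assert rec.return_date == dt.date(2022, 3, 1) + dt.timedelta(days=58)
        assert len(rec.stops) == 2
        assert sorted(s.duration_days for s in rec.stops) == [12, 30]
        labels = [p[0] for p in rec.phases]
        assert labels[0] == "home" and labels[-1] == "home"
        assert "pastoral" in labels and "agropastoral-1" in labels

    def test_resident_track_never_departs(self):
        rng = np.random.default_rng(3)
        ts = pd.date_range("2022-03-01", periods=30 * 12, freq="2h")
        track = pd.DataFrame({"timestamp": ts,
                              "lat": 14.5 + rng.normal(0, 5e-3, len(ts)),
                              "lon": -16.5 + rng.normal(0, 5e-3, len(ts))})
        home = Point(-16.5, 14.5).buffer(0.03)
        rec = summaries.detect_stops_and_phases(track, home)
        assert rec.departure is None and rec.return_date is None
        assert rec.phases[0][0] == "home"

    def test_time_shift_invariance(self):
        track = _journey_track()
        home = Point(-16.5, 14.5).buffer(0.03)
        a = summaries.detect_stops_and_phases(track, home)
        shifted = track.copy()
        shifted["timestamp"] = shifted["timestamp"] + pd.Timedelta(days=40)
        b = summaries.detect_stops_and_phases(shifted, home)
        assert (b.departure - a.departure) == dt.timedelta(days=40)
        assert [s.duration_days for s in a.stops] == [
            s.duration_days for s in b.stops
        ]

    def test_synthetic_transhumant_departure_recovered(self, ref_model):
        cfg = hh.SimConfig(n_herds=1, n_days=120, seed=23,
                           herd_types=("transhumant",))
        survey = hh.simulate_survey(cfg, ref_model)
        track = survey.gps.copy()
        track["timestamp"] = pd.to_datetime(track["timestamp_utc"])
        home = Point(cfg.home_lon, cfg.home_lat).buffer(0.03)
        rec = summaries.detect_stops_and_phases(track, home,
                                                summaries.StopParams())
        first_phase = cfg.transhumance_schedule[0].start
        assert rec.departure is not None
        assert abs((rec.departure - first_phase).days) <= 1
        assert rec.return_date is not None
        # the home-return march (60 km at travelling speed) takes 3-4 days
        ret_phase = cfg.transhumance_schedule[-1].start
        assert 0 <= (rec.return_date - ret_phase).days <= 6
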