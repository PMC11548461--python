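import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest

import herdhmm as hh
from herdhmm import track_io

GPS_HEADER = "collar_id,timestamp_utc,lat,lon,dop,temperature_c\n"


def _gps_csv(tmp_path, rows):
    p = tmp_path / "gps.csv"
    p.write_text(GPS_HEADER + "".join(rows))
    return p


def _meta_csv(tmp_path, rows=None):
    p = tmp_path / "meta.csv"
    rows = rows or [
        "C1,A1,H1,resident,2022-01-01T00:00:00,2023-01-01T00:00:00\n"
    ]
    p.write_text(
        "collar_id,animal_id,herd_id,herd_type,start_utc,end_utc\n" + "".join(rows)
    )
    return p


def _regular_rows(n, start="2022-01-10T06:00:00", collar="C1", step_min=30):
    t0 = dt.datetime.fromisoformat(start)
    return [
        f"{collar},{(t0 + dt.timedelta(minutes=step_min * i)).isoformat()},"
        f"{14.5 + 1e-4 * i:.6f},-16.500000,1.2,30\n"
        for i in range(n)
    ]


class TestReadGps:
    def test_well_formed_rows_read(self, tmp_path):
        df, report = track_io.read_gps_table(_gps_csv(tmp_path, _regular_rows(5)))
        assert len(df) == 5 and report.n_valid == 5 and not report.issues

    def test_out_of_range_latitude_reported(self, tmp_path):
        rows = _regular_rows(3)
        rows.append("C1,2022-01-10T09:00:00,95.0,-16.5,1.2,30\n")
        df, report = track_io.read_gps_table(_gps_csv(tmp_path, rows))
        assert len(df) == 3
        assert len(report.issues) == 1
        assert "invalid position" in report.issues[0].reason

    def test_bad_timestamp_reported_with_line(self, tmp_path):
        rows = _regular_rows(2)
        rows.insert(1, "C1,not-a-time,14.5,-16.5,1.2,30\n")
        df, report = track_io.read_gps_table(_gps_csv(tmp_path, rows))
        assert len(df) == 2
        assert report.issues[0].line == 3  # 1-based, after the header
        assert "timestamp" in report.issues[0].reason

    def test_duplicates_deduplicated_and_counted(self, tmp_path):
        rows = _regular_rows(4)
        rows.append(rows[1])
        df, report = track_io.read_gps_table(_gps_csv(tmp_path, rows))
        assert len(df) == 4
        assert report.n_duplicates == 1

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("collar_id,timestamp_utc,lat\nC1,2022-01-01T00:00:00,14.5\n")
        with pytest.raises(track_io.SchemaError):
            track_io.read_gps_table(p)


class TestAssignAndSegment:
    def test_gap_splits_into_two_segments(self, tmp_path):
        # 10 fixes, 90-min gap after fix 4 -> segments of 4 and 6
        rows = _regular_rows(4)
        t0 = dt.datetime.fromisoformat("2022-01-10T06:00:00")
        late = t0 + dt.timedelta(minutes=90 + 3 * 30)
        rows += [
            f"C1,{(late + dt.timedelta(minutes=30 * i)).isoformat()},14.5,-16.5,1,30\n"
            for i in range(6)
        ]
        gps, _ = track_io.read_gps_table(_gps_csv(tmp_path, rows))
        meta = track_io.read_metadata(_meta_csv(tmp_path))
        segments, report = track_io.assign_and_segment(gps, meta, min_len=3)
        assert [len(s) for s in segments] == [4, 6]
        assert report.n_usable == 10
        assert report.check_conservation()

    def test_regular_stream_single_segment(self, tmp_path):
        gps, _ = track_io.read_gps_table(_gps_csv(tmp_path, _regular_rows(20)))
        meta = track_io.read_metadata(_meta_csv(tmp_path))
        segments, report = track_io.assign_and_segment(gps, meta, min_len=10)
        assert len(segments) == 1 and len(segments[0]) == 20
        assert report.pct_removed == 0.0

    def test_short_fragment_removed_and_counted(self, tmp_path):
        # an isolated 2-fix island between two gaps is removed under min_len
        rows = _regular_rows(12)
        island = _regular_rows(2, start="2022-01-11T00:00:00")
        tail = _regular_rows(12, start="2022-01-12T00:00:00")
        gps, _ = track_io.read_gps_table(_gps_csv(tmp_path, rows + island + tail))
        meta = track_io.read_metadata(_meta_csv(tmp_path))
        segments, report = track_io.assign_and_segment(gps, meta, min_len=10)
        assert report.removed["short_segment"] == 2
        assert report.n_usable == 24
        assert report.pct_removed == pytest.approx(100 * 2 / 26)
        assert report.check_conservation()

    def test_fixes_outside_assignment_removed(self, tmp_path):
        rows = _regular_rows(15)
        meta = track_io.read_metadata(
            _meta_csv(tmp_path,
                      ["C1,A1,H1,resident,2022-01-10T06:00:00,2022-01-10T11:00:00\n"])
        )
        gps, _ = track_io.read_gps_table(_gps_csv(tmp_path, rows))
        segments, report = track_io.assign_and_segment(gps, meta, min_len=5)
        assert report.removed["outside_assignment"] == 5
        assert report.n_usable == 10
        assert report.check_conservation()

    def test_empty_intersection_returns_empty_with_report(self, tmp_path):
        gps, _ = track_io.read_gps_table(_gps_csv(tmp_path, _regular_rows(5)))
        meta = track_io.read_metadata(
            _meta_csv(tmp_path,
                      ["C9,A9,H9,resident,2022-01-01T00:00:00,2022-02-01T00:00:00\n"])
        )
        segments, report = track_io.assign_and_segment(gps, meta)
        assert segments == []
        assert report.removed["outside_assignment"] == 5
        assert report.check_conservation()

    def test_idempotent_on_clean_segments(self, tmp_path):
        gps, _ = track_io.read_gps_table(_gps_csv(tmp_path, _regular_rows(30)))
        meta = track_io.read_metadata(_meta_csv(tmp_path))
        segs1, _ = track_io.assign_and_segment(gps, meta)
        again = segs1[0].fixes[["collar_id", "timestamp", "lat", "lon"]].copy()
        segs2, report2 = track_io.assign_and_segment(again, meta)
        assert len(segs2) == 1
        assert report2.pct_removed == 0.0
        pd.testing.assert_frame_equal(
            segs1[0].fixes[["timestamp", "lat", "lon"]],
            segs2[0].fixes[["timestamp", "lat", "lon"]],
        )

    def test_survey_conservation_identity(self, small_survey):
        gps, _read = track_io.read_gps_table(io_from_df(small_survey.gps))
        meta = track_io.read_metadata(io_from_df(small_survey.metadata))
        _, report = track_io.assign_and_segment(gps, meta)
        assert report.check_conservation()
        assert 0.0 <= report.pct_removed < 100.0


def io_from_df(df):
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestLabelTime:
    def test_mid_january_is_cold_dry(self):
        labels = track_io.label_time(
            [dt.datetime(2023, 1, 15, 12, 0)], centre=(14.5, -16.5)
        )
        assert labels["season"].iloc[0] == "cold_dry"

    def test_season_boundaries(self):
        months = {2: "cold_dry", 3: "warm_dry", 5: "warm_dry", 6: "rainy",
                  10: "rainy", 11: "cold_dry"}
        for m, season in months.items():
            lab = track_io.label_time([dt.datetime(2022, m, 10)], (14.5, -16.5))
            assert lab["season"].iloc[0] == season

    def test_solar_noon_is_day_and_midnight_night(self):
        # local solar noon at lon -16.5 is ~13:06 UTC
        lab = track_io.label_time(
            [dt.datetime(2022, 6, 10, 13, 6), dt.datetime(2022, 6, 10, 1, 0)],
            (14.5, -16.5),
        )
        assert list(lab["diel"]) == ["day", "night"]

    def test_polar_centre_rejected(self):
        with pytest.raises(ValueError):
            track_io.label_time([dt.datetime(2022, 6, 1)], (75.0, 0.0))
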