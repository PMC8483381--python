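import io

import numpy as np
import pandas as pd
import pytest

from fptnsd.telemetry import (FormatConfig, FormatError, CaribouYear,
                              filter_implausible_fixes, project_to_plane,
                              read_telemetry, resample_to_interval,
                              split_analysis_years, qc_report)
from .conftest import TZ, make_track, make_year


CSV = """animal_id,timestamp,lon,lat
A,2004-07-01T00:00:00Z,-153.5,70.6
B,2004-07-01T01:00:00Z,-153.6,70.5
A,2004-07-01T02:00:00Z,-153.4,70.6
A,2004-07-01T02:00:00Z,-153.9,70.9
B,2004-07-01T03:00:00Z,-153.7,70.5
A,2004-07-01T04:00:00Z,-153.3,70.6
"""


class TestReadTelemetry:
    def test_interleaved_animals_split_and_sorted(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(CSV)
        trajs = read_telemetry(p)
        assert [t.animal_id for t in trajs] == ["A", "B"]
        a = trajs[0]
        assert len(a) == 3  # duplicate timestamp dropped, first kept
        assert a.df["t"].is_monotonic_increasing
        assert list(a.dropped["reason"]) == ["duplicate"]
        assert float(a.df["lon"].iloc[1]) == -153.4  # first record wins
        assert len(trajs[1]) == 2

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("animal_id,timestamp,lon\nA,2004-07-01T00:00:00Z,-153.5\n")
        with pytest.raises(FormatError, match="lat"):
            read_telemetry(p)

    def test_unparseable_timestamp_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("animal_id,timestamp,lon,lat\n"
                     "A,2004-07-01T00:00:00Z,-153.5,70.6\n"
                     "A,not-a-time,-153.5,70.6\n")
        with pytest.raises(FormatError, match="line 3"):
            read_telemetry(p)


class TestSpikeFilter:
    def test_straight_slow_path_unchanged(self):
        xy = [(i * 2.0, 0.0) for i in range(20)]  # 2 km / 12 h
        traj = make_track(xy)
        out = filter_implausible_fixes(traj)
        assert len(out) == 20

    def test_teleport_spike_removed(self):
        xy = [(i * 2.0, 0.0) for i in range(20)]
        xy[10] = (20.0, 200.0)  # 200 km off-track for one fix
        traj = make_track(xy, interval_h=2.0)
        out = filter_implausible_fixes(traj)
        assert len(out) == 19
        assert not np.any(out.df["y"].to_numpy() > 100_000)

    def test_injected_spikes_exactly_removed(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 0.5, (120, 2)), axis=0)  # slow wander
        spike_at = [15, 50, 90]
        for i in spike_at:
            xy[i] = xy[i] + np.array([300.0, 300.0])
        traj = make_track(xy, interval_h=2.0)
        out = filter_implausible_fixes(traj)
        kept_x = set(np.round(out.df["x"].to_numpy(), 3))
        assert len(out) == 120 - len(spike_at)
        for i in spike_at:
            assert round(xy[i][0] * 1000.0, 3) not in kept_x

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(4)
        xy = np.cumsum(rng.normal(0, 0.5, (60, 2)), axis=0)
        xy[30] += 250.0
        once = filter_implausible_fixes(make_track(xy, interval_h=2.0))
        twice = filter_implausible_fixes(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestAnalysisYears:
    def test_single_year_span(self):
        n = 365 * 2  # 12-h fixes over one analysis-year
        xy = [(0.0, 0.0)] * n
        traj = make_track(xy, start="2004-07-01 00:00")
        ys = split_analysis_years(traj)
        assert len(ys) == 1
        assert ys[0].year_start == pd.Timestamp(2004, 7, 1, tz=TZ)
        assert ys[0].passed_qc

    def test_two_years_partitioned_at_july_first(self):
        n = 500 * 2
        xy = [(0.0, 0.0)] * n
        traj = make_track(xy, start="2004-07-01 00:00")
        ys = split_analysis_years(traj)
        assert [cy.year for cy in ys] == [2004, 2005]
        for cy in ys:
            assert (cy.df["t"] >= cy.year_start).all()

    def test_290_day_and_gap_screens(self):
        # 295 days, worst gap 3 days -> passes
        t_ok = np.concatenate([np.arange(0, 100 * 24, 12.0),
                               np.arange(103 * 24, 295 * 24, 12.0)])
        # 300 days containing one 16-day gap -> fails
        t_bad = np.concatenate([np.arange(0, 100 * 24, 12.0),
                                np.arange(116 * 24, 300 * 24, 12.0)])
        for hours, expect in [(t_ok, True), (t_bad, False)]:
            start = pd.Timestamp(2004, 7, 1, tz=TZ)
            df = pd.DataFrame({
                "t": start + pd.to_timedelta(hours, unit="h"),
                "lon": 0.0, "lat": 0.0, "x": 0.0, "y": 0.0})
            traj = make_track([(0, 0), (1, 1)])
            traj.df = df
            cy = split_analysis_years(traj)[0]
            assert cy.passed_qc is expect

    def test_qc_report_shape(self, small_population):
        _, years, _ = small_population
        rep = qc_report(years)
        assert set(rep.columns) >= {"animal_id", "year", "duration_days",
                                    "max_gap_days", "passed_qc"}
        assert len(rep) == len(years)


class TestResample:
    def _dense_year(self, interval_h=2.0, days=30):
        hours = np.arange(0, days * 24, interval_h)
        xy = np.column_stack([hours * 0.1, np.zeros_like(hours)])
        start = pd.Timestamp(2004, 7, 1, tz=TZ)
        df = pd.DataFrame({"t": start + pd.to_timedelta(hours, unit="h"),
                           "lon": 0.0, "lat": 0.0,
                           "x": xy[:, 0] * 1000, "y": 0.0})
        from fptnsd.telemetry import _make_year
        return _make_year("A", start, df, interval_h=interval_h)

    def test_two_hour_to_twelve_hour_two_per_day(self):
        out = resample_to_interval(self._dense_year(), 12.0)
        per_day = out.df.groupby(out.df["t"].dt.date).size()
        assert per_day.max() <= 2
        # interior days sit exactly on the 00:00 / 12:00 grid
        dates = sorted(set(out.df["t"].dt.date))
        interior = out.df[out.df["t"].dt.date.isin(dates[1:-1])]
        assert set(interior["t"].dt.hour) <= {0, 12}

    def test_idempotent_at_native_interval(self):
        cy = self._dense_year(interval_h=12.0)
        out = resample_to_interval(cy, 12.0)
        assert len(out) == len(cy)
        pd.testing.assert_series_equal(out.df["t"], cy.df["t"])

    def test_outage_filled_by_nearest_within_tolerance(self):
        cy = self._dense_year(interval_h=2.0, days=4)
        # drop fixes 09:00-15:00 on day 1: noon slot takes nearest survivor
        keep = ~((cy.df["t"].dt.dayofyear == cy.df["t"].dt.dayofyear.iloc[0])
                 & cy.df["t"].dt.hour.between(9, 15))
        cy.df = cy.df[keep].reset_index(drop=True)
        out = resample_to_interval(cy, 12.0, tolerance_h=6.0)
        day0 = out.df[out.df["t"].dt.date == cy.df["t"].dt.date.iloc[0]]
        # oracle: nearest remaining fix to 12:00 is the 08:00 or 16:00 one
        noonish = day0[day0["t"].dt.hour.between(6, 18)]
        assert len(noonish) == 1
        assert noonish["t"].dt.hour.iloc[0] in (8, 16)

    def test_never_increases_fix_count_or_path_length(self, small_population):
        _, years, _ = small_population
        for cy in years[:5]:
            out = resample_to_interval(cy, 24.0)
            assert len(out) <= len(cy)
            for a in (cy, out):
                a.path = np.sum(np.hypot(np.diff(a.df["x"]), np.diff(a.df["y"])))
            assert out.path <= cy.path + 1e-9


def test_project_to_plane_round_trips(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(CSV)
    traj = project_to_plane(read_telemetry(p)[0])
    assert {"x", "y"} <= set(traj.df.columns)
    from fptnsd.projection import DEFAULT_PROJECTION
    lon, lat = DEFAULT_PROJECTION.inverse(traj.df["x"].to_numpy(),
                                     traj.df["y"].to_numpy())
    assert np.allclose(lon, traj.df["lon"], atol=1e-8)
    assert np.allclose(lat, traj.df["lat"], atol=1e-8)
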