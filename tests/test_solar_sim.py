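import math

import numpy as np
import pandas as pd
import pytest

from striplight import geometry as g, solar_sim as ss


def _m2s3():
    t = g.build_treatment("M2S3")
    return g.split_strip(t), g.row_positions(t)


class TestSolarPosition:
    def test_equinox_noon_elevation(self):
        # declination ~0: noon elevation = 90 - latitude
        sp = ss.solar_position(36.7064, ss.SITE_LONGITUDE, "2023-09-23 12:00", utc_offset=8)
        assert sp.elevation == pytest.approx(90 - 36.71, abs=0.5)

    def test_noon_azimuth_south(self):
        sp = ss.solar_position(ss.SITE_LATITUDE, ss.SITE_LONGITUDE,
                               "2023-08-01 12:10", utc_offset=8)
        assert sp.azimuth == pytest.approx(180.0, abs=5.0)

    def test_midnight_below_horizon(self):
        sp = ss.solar_position(ss.SITE_LATITUDE, ss.SITE_LONGITUDE,
                               "2023-08-01 00:00", utc_offset=8)
        assert sp.elevation < 0

    def test_naive_timestamp_requires_offset(self):
        with pytest.raises(ValueError, match="utc_offset"):
            ss.solar_position(36.7, 119.1, "2023-08-01 12:00")

    def test_tz_aware_timestamp_accepted(self):
        sp = ss.solar_position(36.7, 119.1, pd.Timestamp("2023-08-01 12:00", tz="Asia/Shanghai"))
        assert sp.elevation > 50


class TestShadowOffset:
    def test_sun_due_east_45deg(self):
        sun = ss.SolarPosition(45.0, 90.0, pd.Timestamp("2023-08-01 08:00"))
        assert ss.shadow_offset(2.6, 0.8, sun) == pytest.approx(1.8)

    def test_overhead_sun_casts_nothing(self):
        sun = ss.SolarPosition(90.0, 180.0, pd.Timestamp("2023-08-01 12:00"))
        assert ss.shadow_offset(2.6, 0.8, sun) == pytest.approx(0.0, abs=1e-12)

    def test_sun_parallel_to_rows(self):
        sun = ss.SolarPosition(30.0, 180.0, pd.Timestamp("2023-08-01 12:00"))
        assert ss.shadow_offset(2.6, 0.8, sun, row_azimuth=180.0) == pytest.approx(0.0, abs=1e-12)

    def test_night_means_infinite_reach(self):
        sun = ss.SolarPosition(-5.0, 90.0, pd.Timestamp("2023-08-01 05:00"))
        assert math.isinf(ss.shadow_offset(2.6, 0.8, sun))

    def test_reach_decreases_with_elevation(self):
        reaches = [ss.shadow_offset(2.6, 0.8, ss.SolarPosition(el, 90.0, pd.Timestamp("2023-08-01")))
                   for el in (10, 30, 50, 70, 89)]
        assert all(b < a for a, b in zip(reaches, reaches[1:]))


class TestSimulateDay:
    def test_unshadowed_point_conserves_daily_total(self):
        geom, _ = _m2s3()
        sky = ss.SkyModel(daily_total=8.0, pm_attenuation=0.4)
        ref = ss.simulate_day(geom, [g.RowLayout(1, 0.0, "east", 99.0)], sky,
                              "2023-08-15", maize_rows=())[0]
        integral = ref.par.sum() * 900 / (ss.UMOL_PER_J * 1e6)
        assert integral == pytest.approx(8.0, rel=0.01)

    def test_no_maize_means_identical_rows(self):
        t = g.build_treatment("M2S4")
        geom = g.split_strip(t).with_heights(0.8, 0.8)   # soybean-height maize: no walls
        layout = g.row_positions(t)
        series = ss.simulate_day(geom, layout, ss.SkyModel(10.0), "2023-08-15")
        for s in series[1:]:
            np.testing.assert_allclose(s.par, series[0].par)

    def test_east_west_mirror_symmetry(self):
        # mirroring the row positions inside the cell swaps the series
        geom, layout = _m2s3()
        period = geom.width
        sky = ss.SkyModel(10.0)
        fwd = ss.simulate_day(geom, layout, sky, "2023-08-15")
        mirrored = [g.RowLayout(r.row_index, (0.4 - (r.cross_row_position - 0.0)) % period,
                                r.role, r.distance_to_nearest_maize_row)
                    for r in layout]
        back = ss.simulate_day(geom, mirrored, sky, "2023-08-15")
        # the mirror of row at x sees the time-reflection (about solar noon)
        # of the original row's day
        for s_f, s_b in zip(fwd, back):
            reflected = np.roll(s_b.par[::-1], 1)
            np.testing.assert_allclose(s_f.par, reflected, rtol=2e-3, atol=1.0)

    def test_edge_rows_lose_relative_to_middle(self):
        geom, layout = _m2s3()
        series = ss.simulate_day(geom, layout, ss.SkyModel(10.0), "2023-08-15")
        sums = {s.row_index: s.daily_sum() for s in series}
        assert sums[2] > sums[1] and sums[2] > sums[3]

    def test_cloud_must_match_cadence(self):
        geom, layout = _m2s3()
        with pytest.raises(ValueError, match="96"):
            ss.simulate_day(geom, layout, ss.SkyModel(10.0), "2023-08-15",
                            cloud=np.ones(10))


class TestPeakTime:
    def _series(self, par, start="2023-08-15 00:00"):
        times = pd.date_range(start, periods=len(par), freq="15min")
        return ss.SensorSeries(row_index=1, times=times, par=np.asarray(par, float))

    def test_symmetric_triangle_peaks_at_center(self):
        par = np.concatenate([np.arange(10), [10.0], np.arange(10)[::-1]])
        s = self._series(par, start="2023-08-15 09:30")
        assert ss.peak_time(s) == pd.Timestamp("2023-08-15 12:00")

    def test_unique_maximum(self):
        par = np.zeros(96)
        par[46] = 5.0  # 11:30
        s = self._series(par)
        assert ss.peak_time(s, smoothing_window=1) == pd.Timestamp("2023-08-15 11:30")

    def test_tie_breaks_earlier(self):
        par = np.zeros(96)
        par[40:48] = 7.0
        s = self._series(par)
        assert ss.peak_time(s, smoothing_window=1) == pd.Timestamp("2023-08-15 10:00")

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            ss.peak_time(self._series(np.zeros(96)))

    def test_simulated_west_peak_not_after_east_peak(self):
        geom, layout = _m2s3()
        series = ss.simulate_day(geom, layout, ss.SkyModel(10.0, pm_attenuation=0.7),
                                 "2023-08-15")
        east = ss.peak_time(series[0])
        west = ss.peak_time(series[-1])
        assert west <= east


class TestSensorIO:
    def test_roundtrip(self, tmp_path):
        geom, layout = _m2s3()
        series = ss.simulate_day(geom, layout, ss.SkyModel(10.0), "2023-08-15")
        path = tmp_path / "sensors.csv"
        ss.write_sensor_csv(series, path)
        back = ss.read_sensor_csv(path)
        assert [s.row_index for s in back] == [1, 2, 3]
        for a, b in zip(series, back):
            np.testing.assert_allclose(a.par, b.par, atol=1e-4)

    def test_hobo_export_with_row_in_filename(self, tmp_path):
        p = tmp_path / "M2S3_row2.csv"
        times = pd.date_range("2023-08-15", periods=8, freq="15min")
        pd.DataFrame({"timestamp": times, "intensity": np.arange(8.0)}).to_csv(p, index=False)
        s = ss.read_hobo_csv(p)
        assert s.row_index == 2 and len(s.par) == 8

    def test_cadence_enforced(self):
        times = pd.date_range("2023-08-15", periods=4, freq="10min")
        with pytest.raises(ValueError, match="cadence"):
            ss.SensorSeries(row_index=1, times=times, par=np.ones(4))
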