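import numpy as np
import pytest

from topotreeline.topoclimate import (
    HourlyMetSeries,
    UndefinedIndexError,
    frost_index,
    insolation,
    monthly_summaries,
    partition_day_night,
    photoinhibition_index,
    read_hourly_csv,
    site_maxima,
    summaries_table,
    summer_desiccation_index,
    winter_desiccation_index,
    write_hourly_csv,
)

from conftest import random_series


def tiny_series(temp, wind, rh, solar, netrad, **kw):
    """Series from explicit per-hour values (any length)."""
    return HourlyMetSeries(
        site_id=kw.get("site", "s"),
        point_id=kw.get("point", "p"),
        month_label=kw.get("month", "jan"),
        temp_c=np.asarray(temp, float),
        wind_ms=np.asarray(wind, float),
        rh_pct=np.asarray(rh, float),
        solar_wm2=np.asarray(solar, float),
        netrad_wm2=np.asarray(netrad, float),
    )


def naive_indices(series, t_max, ws_max, threshold=1.0):
    """Per-hour loop oracle for all five indices."""
    photo = desic_s = desic_w = frost = insol = 0.0
    n_day = n_night = 0
    for t, w, rh, sol, net in zip(
        series.temp_c, series.wind_ms, series.rh_pct,
        series.solar_wm2, series.netrad_wm2,
    ):
        if sol > threshold:
            n_day += 1
            photo += (t_max - t) * sol
            desic_s += t * w * (100 - rh)
            insol += sol
        else:
            n_night += 1
            frost += (t_max - t) * (ws_max - w) * (-net)
        desic_w += (t_max - t) * w * (100 - rh)
    n = n_day + n_night
    return {
        "photo": photo / n_day if n_day else None,
        "desic_summer": desic_s / n_day if n_day else None,
        "desic_winter": desic_w / n,
        "frost": frost / n_night if n_night else None,
        "insolation": insol,
    }


class TestPartition:
    def test_all_dark_and_all_bright(self):
        n = 48
        dark = tiny_series([5] * n, [1] * n, [50] * n, [0] * n, [-60] * n)
        assert partition_day_night(dark).n_daytime == 0
        bright = tiny_series([5] * n, [1] * n, [50] * n, [300] * n, [200] * n)
        p = partition_day_night(bright)
        assert p.n_nighttime == 0 and p.n_total == n

    def test_counts_are_consistent(self):
        s = random_series(1)
        p = partition_day_night(s)
        assert p.n_daytime + p.n_nighttime == p.n_total == s.n_hours
        assert p.daytime.sum() == p.n_daytime


class TestSiteMaxima:
    def test_single_and_multiple_series(self):
        a = tiny_series([10, 10], [2, 3], [50, 50], [0, 0], [-50, -50])
        b = tiny_series([12, 15], [1, 7], [50, 50], [0, 0], [-50, -50], point="q")
        assert site_maxima([a]).t_site_max == 10
        m = site_maxima([a, b])
        assert (m.t_site_max, m.ws_site_max) == (15, 7)

    def test_matches_bruteforce_scan(self):
        group = [random_series(i, point=f"p{i}") for i in range(4)]
        m = site_maxima(group)
        assert m.t_site_max == max(float(t) for s in group for t in s.temp_c)
        assert m.ws_site_max == max(float(w) for s in group for w in s.wind_ms)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            site_maxima([])


class TestIndexFormulas:
    def test_photoinhibition_hand_value(self):
        # two daytime hours: (20-10)*500 + (20-15)*800 = 9000; / 2 = 4500
        s = tiny_series([10, 15], [1, 1], [50, 50], [500, 800], [400, 700])
        m = site_maxima([s])
        assert m.t_site_max == 15
        p = partition_day_night(s)
        from topotreeline.topoclimate import SiteMaxima

        m20 = SiteMaxima("s", "jan", 20.0, 10.0)
        assert photoinhibition_index(s, m20, p) == pytest.approx(4500.0)

    def test_photoinhibition_zero_when_temp_at_site_max(self):
        s = tiny_series([20, 20], [1, 1], [50, 50], [500, 800], [400, 700])
        m = site_maxima([s])
        p = partition_day_night(s)
        assert photoinhibition_index(s, m, p) == 0.0

    def test_photoinhibition_linear_in_solar(self):
        s1 = tiny_series([10, 15], [1, 1], [50, 50], [500, 800], [1, 1])
        s2 = tiny_series([10, 15], [1, 1], [50, 50], [1000, 1600], [1, 1])
        from topotreeline.topoclimate import SiteMaxima

        m = SiteMaxima("s", "jan", 20.0, 10.0)
        v1 = photoinhibition_index(s1, m, partition_day_night(s1))
        v2 = photoinhibition_index(s2, m, partition_day_night(s2))
        assert v2 == pytest.approx(2 * v1)

    def test_summer_desiccation_hand_value_and_zeros(self):
        # one daytime hour: 20 * 5 * (100-40) = 6000
        s = tiny_series([20], [5], [40], [600], [500])
        assert summer_desiccation_index(s, partition_day_night(s)) == 6000.0
        saturated = tiny_series([20], [5], [100], [600], [500])
        assert summer_desiccation_index(saturated, partition_day_night(saturated)) == 0.0
        calm = tiny_series([20], [0], [40], [600], [500])
        assert summer_desiccation_index(calm, partition_day_night(calm)) == 0.0

    def test_winter_desiccation_both_hour_sets(self):
        # day hour: (5-0)*10*30 = 1500; night hour: (5+5)*10*20 = 2000
        s = tiny_series([0, -5], [10, 10], [70, 80], [400, 0], [300, -80])
        from topotreeline.topoclimate import SiteMaxima

        m = SiteMaxima("s", "jul", 5.0, 12.0)
        p = partition_day_night(s)
        assert winter_desiccation_index(s, m, p) == pytest.approx(1750.0)
        assert winter_desiccation_index(s, m, p, "daytime_only") == pytest.approx(750.0)

    def test_winter_desiccation_zero_at_site_max_temperature(self):
        s = tiny_series([5, 5], [10, 10], [70, 80], [400, 0], [300, -80])
        from topotreeline.topoclimate import SiteMaxima

        m = SiteMaxima("s", "jul", 5.0, 12.0)
        assert winter_desiccation_index(s, m, partition_day_night(s)) == 0.0

    def test_frost_hand_value_and_zero_cases(self):
        # one night hour: (15-(-2)) * (12-2) * 80 = 13600
        s = tiny_series([-2], [2], [80], [0], [-80])
        from topotreeline.topoclimate import SiteMaxima

        m = SiteMaxima("s", "jul", 15.0, 12.0)
        assert frost_index(s, m, partition_day_night(s)) == pytest.approx(13600.0)
        windy = tiny_series([-2], [12], [80], [0], [-80])
        assert frost_index(windy, m, partition_day_night(windy)) == 0.0

    def test_frost_nonnegative_under_negative_night_netrad(self):
        s = random_series(7)
        m = site_maxima([s])
        assert frost_index(s, m, partition_day_night(s)) >= 0.0

    def test_insolation_sum_and_night_invariance(self):
        s = tiny_series([5] * 3, [1] * 3, [50] * 3, [100, 500, 300], [50, 400, 200])
        assert insolation(s, partition_day_night(s)) == 900.0
        dark = tiny_series([5], [1], [50], [0], [-200])
        assert insolation(dark, partition_day_night(dark)) == 0.0

    def test_undefined_hour_sets_raise(self):
        dark = tiny_series([5] * 24, [1] * 24, [50] * 24, [0] * 24, [-60] * 24)
        m = site_maxima([dark])
        p = partition_day_night(dark)
        with pytest.raises(UndefinedIndexError):
            photoinhibition_index(dark, m, p)
        with pytest.raises(UndefinedIndexError):
            summer_desiccation_index(dark, p)
        bright = tiny_series([5] * 24, [1] * 24, [50] * 24, [300] * 24, [200] * 24)
        with pytest.raises(UndefinedIndexError):
            frost_index(bright, site_maxima([bright]), partition_day_night(bright))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_vectorised_indices_match_per_hour_loop(self, seed):
        s = random_series(seed)
        m = site_maxima([s])
        p = partition_day_night(s)
        want = naive_indices(s, m.t_site_max, m.ws_site_max)
        assert photoinhibition_index(s, m, p) == pytest.approx(want["photo"], rel=1e-10)
        assert summer_desiccation_index(s, p) == pytest.approx(
            want["desic_summer"], rel=1e-10
        )
        assert winter_desiccation_index(s, m, p) == pytest.approx(
            want["desic_winter"], rel=1e-10
        )
        assert frost_index(s, m, p) == pytest.approx(want["frost"], rel=1e-10)
        assert insolation(s, p) == pytest.approx(want["insolation"], rel=1e-10)

    def test_lowering_temperature_weakly_increases_stress_indices(self):
        s = random_series(3)
        m = site_maxima([s])
        p = partition_day_night(s)
        colder = tiny_series(
            s.temp_c - 5.0, s.wind_ms, s.rh_pct, s.solar_wm2, s.netrad_wm2
        )
        assert photoinhibition_index(colder, m, p) >= photoinhibition_index(s, m, p)
        assert winter_desiccation_index(colder, m, p) >= winter_desiccation_index(s, m, p)
        assert frost_index(colder, m, p) >= frost_index(s, m, p)


class TestMonthlySummaries:
    def test_constant_series(self):
        s = tiny_series([5] * 24, [2] * 24, [60] * 24, [0] * 24, [-50] * 24)
        out = monthly_summaries(s, partition_day_night(s))
        assert out["temp_min"] == out["temp_max"] == 5.0
        assert out["frost_hours"] == 0.0
        assert out["net_longwave"] == 50.0

    def test_frost_hours_and_rain_days_counts(self):
        temp = np.full(72, 4.0)
        temp[10:22] = -1.0  # 12 sub-zero hours
        s = HourlyMetSeries(
            site_id="s", point_id="p", month_label="jul",
            temp_c=temp, wind_ms=np.full(72, 2.0), rh_pct=np.full(72, 60.0),
            solar_wm2=np.zeros(72), netrad_wm2=np.full(72, -40.0),
            rain_mm=np.array([0.0, 0.5, 3.0]),
        )
        out = monthly_summaries(s, partition_day_night(s))
        assert out["frost_hours"] == 12.0
        assert out["rain_days"] == 2.0

    def test_all_day_series_has_undefined_longwave(self):
        s = tiny_series([5] * 24, [1] * 24, [50] * 24, [300] * 24, [200] * 24)
        with pytest.raises(UndefinedIndexError):
            monthly_summaries(s, partition_day_night(s))

    def test_summaries_table_is_wide_with_both_months(self):
        series = [
            random_series(1, month="jan"),
            random_series(2, month="jul"),
            random_series(3, point="q", month="jan"),
            random_series(4, point="q", month="jul"),
        ]
        wide = summaries_table(series)
        assert len(wide) == 2
        assert {"jan_temp_min", "jul_rain_days", "jan_total_solar"} <= set(wide.columns)
        assert wide.shape[1] == 2 + 20


class TestCsvRoundTrip:
    def test_write_then_read_recovers_series(self, tmp_path):
        series = [random_series(5, month="jan"), random_series(6, point="q", month="jul")]
        write_hourly_csv(series, tmp_path / "met.csv")
        back = read_hourly_csv(tmp_path / "met.csv")
        back_by_key = {(s.point_id, s.month_label): s for s in back}
        for s in series:
            b = back_by_key[(s.point_id, s.month_label)]
            np.testing.assert_allclose(b.temp_c, s.temp_c)
            np.testing.assert_allclose(b.rain_mm, s.rain_mm)
            np.testing.assert_allclose(b.netrad_wm2, s.netrad_wm2)
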