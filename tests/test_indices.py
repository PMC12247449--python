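"""Solar geometry, Hargreaves ETp, aridity index, and EDH day counts."""

import numpy as np
import pandas as pd
import pytest

import edhwheat.indices as idx
from edhwheat import (
    aridity_index,
    compute_edh_field,
    count_compound_days,
    count_dry_days,
    count_heat_days,
    extraterrestrial_radiation,
    hargreaves_etp,
)
from conftest import make_climate


def naive_counts(tmax, ai, dates, year):
    """Independent day-by-day loop oracle for HC/DC/CDHC."""
    hc = dc = cdhc = 0
    for t, a, d in zip(tmax, ai, pd.DatetimeIndex(dates)):
        if d.year != year or not (3 <= d.month <= 9):
            continue
        hot = t > 30.0
        dry = (not np.isnan(a)) and a < 0.2
        hc += hot
        dc += dry
        cdhc += hot and dry
    return hc, dc, cdhc


class TestExtraterrestrialRadiation:
    def test_equator_equinox_value(self):
        # At the equator with delta=0: H=pi/2, sinH=1, so Ra = (S0/pi)*(r0/r)^2.
        # Remove the distance factor to compare against S0/pi exactly.
        doy = 81  # late March, delta ~ 0
        ra = extraterrestrial_radiation(0.0, doy)
        dr2 = idx.inverse_distance_squared(doy)
        delta = idx.solar_declination(doy)
        expected = (118.02 / np.pi) * dr2 * np.cos(delta)  # exact at phi=0
        assert ra == pytest.approx(expected, abs=1e-9)
        assert ra / dr2 == pytest.approx(118.02 / np.pi, rel=2e-3)

    def test_polar_night_is_zero(self):
        assert extraterrestrial_radiation(80.0, 355) == 0.0
        assert extraterrestrial_radiation(-80.0, 172) == 0.0

    def test_hemispheric_symmetry(self):
        # Ra(phi, doy) equals Ra(-phi, doy') where doy' has the negated
        # declination (half a year away).
        for doy, mirror in [(1, 183), (100, 282), (200, 17)]:
            d1, d2 = idx.solar_declination(doy), idx.solar_declination(mirror)
            if abs(d1 + d2) > 1e-3:
                continue
            r1 = extraterrestrial_radiation(35.0, doy) / idx.inverse_distance_squared(doy)
            r2 = extraterrestrial_radiation(-35.0, mirror) / idx.inverse_distance_squared(mirror)
            assert r1 == pytest.approx(r2, rel=2e-2)

    def test_latitude_out_of_range(self):
        with pytest.raises(ValueError):
            extraterrestrial_radiation(95.0, 100)


class TestHargreaves:
    def test_zero_cases(self):
        assert hargreaves_etp(15.0, 15.0, 30.0) == 0.0
        assert hargreaves_etp(25.0, 15.0, 0.0) == 0.0

    def test_hand_value(self):
        # 0.0023 * 0.408 * 37.566 * sqrt(10) * (25 + 17.8)
        assert hargreaves_etp(30.0, 20.0, 37.566) == pytest.approx(4.772, abs=1e-3)

    def test_cold_floor(self):
        # mean temperature below -17.8 degC would go negative; floored at 0
        assert hargreaves_etp(-19.0, -21.0, 10.0) == 0.0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            hargreaves_etp(10.0, 12.0, 30.0)


class TestAridityIndex:
    def test_boundary_and_guard(self):
        assert aridity_index(0.0, 5.0) == 0.0
        assert aridity_index(1.0, 5.0) == pytest.approx(0.2)
        assert np.isnan(aridity_index(3.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            aridity_index(-1.0, 5.0)


class TestDayCounts:
    def test_constant_series(self, year_2001_dates):
        n = year_2001_dates.size
        assert count_heat_days(np.full(n, 25.0), year_2001_dates, 2001) == 0
        assert count_heat_days(np.full(n, 35.0), year_2001_dates, 2001) == 214
        assert count_dry_days(np.full(n, 0.5), year_2001_dates, 2001) == 0
        assert count_dry_days(np.full(n, 0.0), year_2001_dates, 2001) == 214

    def test_window_excludes_february_in_leap_years(self):
        dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")  # leap
        assert count_heat_days(np.full(dates.size, 35.0), dates, 2000) == 214

    def test_alternating_pattern(self, year_2001_dates):
        dates = year_2001_dates
        tmax = np.where(np.arange(dates.size) % 2 == 0, 29.0, 31.0)
        window = (dates.month >= 3) & (dates.month <= 9)
        expected = int(np.sum(tmax[window] > 30))
        assert count_heat_days(tmax, dates, 2001) == expected

    def test_boundary_values_not_counted(self, year_2001_dates):
        n = year_2001_dates.size
        # strictly-greater / strictly-less thresholds
        assert count_heat_days(np.full(n, 30.0), year_2001_dates, 2001) == 0
        assert count_dry_days(np.full(n, 0.2), year_2001_dates, 2001) == 0

    def test_undefined_ai_days_never_dry(self, year_2001_dates):
        ai = np.full(year_2001_dates.size, np.nan)
        assert count_dry_days(ai, year_2001_dates, 2001) == 0

    def test_compound_disjoint_and_full(self, year_2001_dates):
        n = year_2001_dates.size
        k = np.arange(n)
        tmax = np.where(k % 2 == 0, 35.0, 25.0)
        ai = np.where(k % 2 == 0, 0.5, 0.0)  # dry exactly when not hot
        assert count_compound_days(tmax, ai, year_2001_dates, 2001) == 0
        assert count_compound_days(np.full(n, 35.0), np.zeros(n), year_2001_dates, 2001) == 214

    def test_missing_days_raise(self):
        dates = pd.date_range("2001-01-01", "2001-08-31", freq="D")
        with pytest.raises(ValueError):
            count_heat_days(np.full(dates.size, 20.0), dates, 2001)

    def test_random_series_match_naive_loop(self, year_2001_dates):
        rng = np.random.default_rng(42)
        n = year_2001_dates.size
        for _ in range(100):
            tmax = rng.uniform(20.0, 40.0, n)
            ai = rng.uniform(0.0, 0.5, n)
            ai[rng.uniform(size=n) < 0.05] = np.nan
            hc = count_heat_days(tmax, year_2001_dates, 2001)
            dc = count_dry_days(ai, year_2001_dates, 2001)
            cdhc = count_compound_days(tmax, ai, year_2001_dates, 2001)
            assert (hc, dc, cdhc) == naive_counts(tmax, ai, year_2001_dates, 2001)
            assert cdhc <= min(hc, dc) <= 214

    def test_monotonicity_in_forcing(self, year_2001_dates):
        rng = np.random.default_rng(7)
        n = year_2001_dates.size
        tmax = rng.uniform(25.0, 35.0, n)
        ai = rng.uniform(0.0, 0.4, n)
        hc0 = count_heat_days(tmax, year_2001_dates, 2001)
        cd0 = count_compound_days(tmax, ai, year_2001_dates, 2001)
        # warming the whole series never decreases heat counts
        assert count_heat_days(tmax + 2.0, year_2001_dates, 2001) >= hc0
        assert count_compound_days(tmax + 2.0, ai, year_2001_dates, 2001) >= cd0
        # wetting (raising AI) never increases dry counts
        dc0 = count_dry_days(ai, year_2001_dates, 2001)
        assert count_dry_days(ai + 0.1, year_2001_dates, 2001) <= dc0


class TestGridField:
    def test_vectorized_equals_scalar_path(self):
        dates = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        rng = np.random.default_rng(3)
        tmax = rng.uniform(20.0, 38.0, (2, 2, dates.size))
        tmin = tmax - rng.uniform(5.0, 12.0, tmax.shape)
        precip = np.where(rng.uniform(size=tmax.shape) < 0.5, 0.0,
                          rng.gamma(0.8, 4.0, tmax.shape))
        clim = make_climate(tmax, dates, lat=[35.0, 45.0], lon=[-100.0, -99.0],
                            tmin=tmin, precip=precip)
        edh = compute_edh_field(clim)
        assert edh["hc"].shape == (2, 2, 2)
        assert (edh["n_days"].values == 214).all()
        # cross-check one cell/year against the scalar operations
        i, j, year = 1, 0, 2002
        doy = dates.dayofyear.values
        ra = extraterrestrial_radiation(45.0, doy)
        etp = hargreaves_etp(tmax[i, j], tmin[i, j], ra)
        ai = aridity_index(precip[i, j], etp)
        assert edh["hc"].values[i, j, 1] == count_heat_days(tmax[i, j], dates, year)
        assert edh["dc"].values[i, j, 1] == count_dry_days(ai, dates, year)
        assert edh["cdhc"].values[i, j, 1] == count_compound_days(tmax[i, j], ai, dates, year)
        assert (edh["cdhc"].values <= np.minimum(edh["hc"].values, edh["dc"].values)).all()

    def test_missing_variable_rejected(self, year_2001_dates):
        clim = make_climate(np.full(year_2001_dates.size, 20.0), year_2001_dates)
        with pytest.raises(ValueError, match="tmin"):
            compute_edh_field(clim.drop_vars("tmin"))
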