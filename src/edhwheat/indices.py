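"""Extreme dry-heat (EDH) climate indices.

Annual day-count indices over the Mar 1 – Sep 30 growing window:

* **HC** — heat condition: days with daily maximum temperature strictly
  above 30 °C.
* **DC** — dry condition: days with aridity index (AI = P / ETp) strictly
  below 0.2, where ETp is Hargreaves potential evapotranspiration.
* **CDHC** — compound dry-heat condition: days that are simultaneously hot
  and dry. No cascading or lag logic is applied.

The window excludes February, so its length N is 214 days in every year,
leap or not.  Supporting quantities: extraterrestrial radiation Ra
(FAO-56 solar geometry), Hargreaves ETp, and the daily aridity index.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "SOLAR_CONSTANT",
    "WINDOW_DAYS",
    "extraterrestrial_radiation",
    "hargreaves_etp",
    "aridity_index",
    "count_heat_days",
    "count_dry_days",
    "count_compound_days",
    "compute_edh_field",
]

#: Solar constant, MJ m⁻² d⁻¹ (daily total on a plane normal to the beam).
SOLAR_CONSTANT = 118.02

#: Days in the Mar 1 – Sep 30 window (February excluded, leap-invariant).
WINDOW_DAYS = 214

#: Heat-day threshold on daily Tmax, °C (strict >).
HEAT_THRESHOLD_C = 30.0

#: Dry-day threshold on the aridity index (strict <).
ARIDITY_THRESHOLD = 0.2

#: ETp below this (mm/day) makes the aridity index undefined.
ETP_EPSILON = 1e-6


def solar_declination(day_of_year):
    """Solar declination δ (radians) for a day of year, FAO-56 form."""
    j = np.asarray(day_of_year, dtype=float)
    return 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)


def inverse_distance_squared(day_of_year):
    """Inverse relative Earth–Sun distance squared (r0/r)², FAO-56 form."""
    j = np.asarray(day_of_year, dtype=float)
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)


def sunset_hour_angle(latitude_rad, declination_rad):
    """Sunset hour angle H ∈ [0, π] radians, clamped for polar day/night."""
    x = -np.tan(latitude_rad) * np.tan(declination_rad)
    return np.arccos(np.clip(x, -1.0, 1.0))


def extraterrestrial_radiation(latitude, day_of_year):
    """Daily extraterrestrial radiation Ra in MJ m⁻² d⁻¹.

    Ra = (S0/π) (r0/r)² [H sinφ sinδ + sinH cosφ cosδ]

    with δ, (r0/r)² and H from the standard FAO-56 formulas.  Under polar
    night H = 0 and both bracket terms vanish, giving Ra = 0.

    Parameters
    ----------
    latitude : array_like
        Geographic latitude in degrees, |φ| ≤ 90.
    day_of_year : array_like
        Day of year, 1–366.  Broadcasts against ``latitude``.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude must be within [-90, 90] degrees")
    doy = np.asarray(day_of_year)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day_of_year must be within [1, 366]")

    phi = np.deg2rad(lat)
    delta = solar_declination(doy)
    dr2 = inverse_distance_squared(doy)
    h = sunset_hour_angle(phi, delta)
    ra = (SOLAR_CONSTANT / np.pi) * dr2 * (
        h * np.sin(phi) * np.sin(delta) + np.sin(h) * np.cos(phi) * np.cos(delta)
    )
    # Tiny negative values can only arise from float round-off at H≈0.
    return np.maximum(ra, 0.0)


def hargreaves_etp(tmax, tmin, ra):
    """Hargreaves potential evapotranspiration, mm/day.

    ETp = 0.0023 · 0.408 · Ra · (Tmax − Tmin)^0.5 · (T + 17.8),
    T = (Tmax + Tmin) / 2.

    The 0.408 factor converts Ra from MJ m⁻² d⁻¹ to mm/day of evaporation
    equivalent.  Floored at 0: the formula only goes negative for mean
    temperature below −17.8 °C, where evaporative demand is nil.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    ra = np.asarray(ra, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax must be >= tmin everywhere")
    tmean = 0.5 * (tmax + tmin)
    etp = 0.0023 * 0.408 * ra * np.sqrt(tmax - tmin) * (tmean + 17.8)
    return np.maximum(etp, 0.0)


def aridity_index(p, etp):
    """Daily aridity index AI = P / ETp (dimensionless).

    Days with ETp ≤ 1e-6 mm/day get NaN (undefined): a frozen or dark day
    with no evaporative demand is not meteorological drought, so such days
    never count as dry.
    """
    p = np.asarray(p, dtype=float)
    etp = np.asarray(etp, dtype=float)
    if np.any(p < 0) or np.any(etp < 0):
        raise ValueError("precipitation and ETp must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(etp > ETP_EPSILON, p / np.maximum(etp, ETP_EPSILON), np.nan)
    return ai


def _window_mask(dates) -> np.ndarray:
    months = dates.month if hasattr(dates, "month") else np.asarray(dates)
    return (np.asarray(months) >= 3) & (np.asarray(months) <= 9)


def _check_window(dates, year: int) -> np.ndarray:
    """Return the positional index of the Mar 1 – Sep 30 window of *year*."""
    import pandas as pd

    idx = pd.DatetimeIndex(dates)
    sel = np.flatnonzero((idx.year == year) & _window_mask(idx))
    if sel.size != WINDOW_DAYS:
        raise ValueError(
            f"Mar 1 - Sep 30 {year} window has {sel.size} days, "
            f"expected {WINDOW_DAYS}; no imputation is performed"
        )
    days = idx[sel]
    if not (days.is_monotonic_increasing and (np.diff(days.values) == np.timedelta64(1, "D")).all()):
        raise ValueError(f"window days for {year} are not consecutive daily values")
    return sel


def count_heat_days(tmax_series, dates, year, threshold=HEAT_THRESHOLD_C):
    """HC: number of Mar 1 – Sep 30 days with Tmax strictly above *threshold* °C."""
    sel = _check_window(dates, year)
    tmax = np.asarray(tmax_series, dtype=float)
    return int(np.sum(tmax[..., sel] > threshold))


def count_dry_days(ai_series, dates, year, threshold=ARIDITY_THRESHOLD):
    """DC: number of window days with AI strictly below *threshold*.

    NaN (undefined AI) days are excluded from the count.
    """
    sel = _check_window(dates, year)
    ai = np.asarray(ai_series, dtype=float)[..., sel]
    return int(np.nansum(ai < threshold))


def count_compound_days(
    tmax_series, ai_series, dates, year,
    heat_threshold=HEAT_THRESHOLD_C, aridity_threshold=ARIDITY_THRESHOLD,
):
    """CDHC: window days simultaneously hot (Tmax > 30) and dry (AI < 0.2)."""
    tmax = np.asarray(tmax_series, dtype=float)
    ai = np.asarray(ai_series, dtype=float)
    if tmax.shape != ai.shape:
        raise ValueError("tmax and AI series are misaligned")
    sel = _check_window(dates, year)
    hot = tmax[..., sel] > heat_threshold
    dry = ai[..., sel] < aridity_threshold  # NaN compares False
    return int(np.sum(hot & np.nan_to_num(dry, nan=0.0).astype(bool)))


def compute_edh_field(
    climate: xr.Dataset,
    heat_threshold: float = HEAT_THRESHOLD_C,
    aridity_threshold: float = ARIDITY_THRESHOLD,
) -> xr.Dataset:
    """Compute the annual HC/DC/CDHC field from a daily climate grid.

    Parameters
    ----------
    climate : xarray.Dataset
        Variables ``tmax``, ``tmin`` (°C) and ``precip`` (mm/day) on dims
        ``(lat, lon, time)`` with a daily ``time`` coordinate and a ``lat``
        coordinate in degrees north.  Every Mar 1 – Sep 30 window of every
        calendar year present must be fully covered.

    Returns
    -------
    xarray.Dataset
        Variables ``hc``, ``dc``, ``cdhc`` (days) on dims
        ``(lat, lon, year)`` plus an ``n_days`` per-year coordinate (always
        214, recorded for completeness).
    """
    import pandas as pd

    for v in ("tmax", "tmin", "precip"):
        if v not in climate:
            raise ValueError(f"climate dataset is missing variable '{v}'")

    times = pd.DatetimeIndex(climate["time"].values)
    doy = times.dayofyear.values
    lat = climate["lat"].values  # degrees

    ra = extraterrestrial_radiation(lat[:, None], doy[None, :])  # (lat, time)
    tmax = climate["tmax"].transpose("lat", "lon", "time").values
    tmin = climate["tmin"].transpose("lat", "lon", "time").values
    precip = climate["precip"].transpose("lat", "lon", "time").values

    etp = hargreaves_etp(tmax, tmin, ra[:, None, :])
    ai = aridity_index(precip, etp)

    hot = tmax > heat_threshold
    with np.errstate(invalid="ignore"):
        dry = (ai < aridity_threshold) & ~np.isnan(ai)

    years = np.unique(times.year.values)
    in_window = _window_mask(times)
    hc = np.empty(hot.shape[:2] + (years.size,), dtype=np.int32)
    dc = np.empty_like(hc)
    cdhc = np.empty_like(hc)
    for k, yr in enumerate(years):
        sel = (times.year.values == yr) & in_window
        if sel.sum() != WINDOW_DAYS:
            raise ValueError(
                f"year {yr}: Mar-Sep window has {int(sel.sum())} days, expected {WINDOW_DAYS}"
            )
        hc[..., k] = hot[..., sel].sum(axis=-1)
        dc[..., k] = dry[..., sel].sum(axis=-1)
        cdhc[..., k] = (hot[..., sel] & dry[..., sel]).sum(axis=-1)

    return xr.Dataset(
        {
            "hc": (("lat", "lon", "year"), hc, {"units": "days", "long_name": "heat-day count (Tmax > 30 degC), Mar-Sep"}),
            "dc": (("lat", "lon", "year"), dc, {"units": "days", "long_name": "dry-day count (AI < 0.2), Mar-Sep"}),
            "cdhc": (("lat", "lon", "year"), cdhc, {"units": "days", "long_name": "compound dry-heat day count, Mar-Sep"}),
        },
        coords={
            "lat": climate["lat"],
            "lon": climate["lon"],
            "year": years,
            "n_days": ("year", np.full(years.size, WINDOW_DAYS, dtype=np.int32)),
        },
        attrs={
            "window": "Mar 1 - Sep 30",
            "heat_threshold_degC": heat_threshold,
            "aridity_threshold": aridity_threshold,
        },
    )
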