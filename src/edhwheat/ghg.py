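"""CO₂-equivalent greenhouse-gas accounting and factorial attribution.

Gas fluxes from wheat soils are expressed in elemental mass (g C for CO₂
and CH₄, g N for N₂O) and converted to CO₂ equivalents with 100-year
global-warming potentials (IPCC AR6: N₂O = 273, CH₄ = 27):

    ECO2 = FCO2 · 44/12
    EN2O = FN2O · 44/28 · 273
    ECH4 = FCH4 · 16/12 · 27
    EGHG = ECO2 + EN2O + ECH4
    GHGI = EGHG / Y

Positive FCO2 is net carbon release (SOC loss); negative is sequestration.
The converters are unit-agnostic linear maps — the caller declares units
(g m⁻², kg ha⁻¹, Tg yr⁻¹ all work identically).

Factor attribution follows the all-drivers-minus-one design: the
contribution of a driver is the all-drivers run minus the run with that
single driver held constant; land-use/land-cover change is isolated as the
difference of a paired run with management frozen.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = [
    "GWP_N2O",
    "GWP_CH4",
    "co2_to_co2eq",
    "n2o_to_co2eq",
    "ch4_to_co2eq",
    "net_ghg",
    "ghgi",
    "ghg_bundle",
    "attribute_factor",
    "attribute_lulc",
    "cell_areas_km2",
    "fit_metrics",
]

GWP_N2O = 273.0  # 100-yr GWP of N2O (AR6)
GWP_CH4 = 27.0   # 100-yr GWP of CH4 (AR6)

#: Yield below this (kg/ha) masks GHGI to avoid division blow-ups.
YIELD_MIN_KG_HA = 1.0


def co2_to_co2eq(fco2):
    """CO₂-C flux → CO₂ equivalents: FCO2 · 44/12."""
    return np.asarray(fco2, dtype=float) / 12.0 * 44.0


def n2o_to_co2eq(fn2o):
    """N₂O-N flux → CO₂ equivalents: FN2O · 44/28 · 273."""
    return np.asarray(fn2o, dtype=float) / 28.0 * 44.0 * GWP_N2O


def ch4_to_co2eq(fch4):
    """CH₄-C flux → CO₂ equivalents: FCH4 · 16/12 · 27."""
    return np.asarray(fch4, dtype=float) / 12.0 * 16.0 * GWP_CH4


def net_ghg(eco2, en2o, ech4):
    """Net GHG emission: EGHG = ECO2 + EN2O + ECH4."""
    return np.asarray(eco2, dtype=float) + np.asarray(en2o, dtype=float) + np.asarray(ech4, dtype=float)


def ghgi(eghg, y, y_min=YIELD_MIN_KG_HA):
    """GHG emission intensity EGHG / Y, masked (NaN) where Y ≤ y_min.

    Negative values are meaningful (net-sink intensity).  Y must be
    non-negative; near-zero yields are masked rather than allowed to blow
    up the ratio, and masked cells propagate as missing downstream.
    """
    eghg = np.asarray(eghg, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("yield must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(y > y_min, eghg / np.maximum(y, y_min), np.nan)
    return out


def ghg_bundle(scenario: xr.Dataset, flux_to_kg_ha: float = 10.0) -> xr.Dataset:
    """Derive per-area CO₂-eq emissions and GHGI from a scenario field.

    Parameters
    ----------
    scenario : xarray.Dataset
        Variables ``yield`` (kg/ha), ``fco2``/``fch4`` (g C m⁻² yr⁻¹) and
        ``fn2o`` (g N m⁻² yr⁻¹) on any common dims.
    flux_to_kg_ha : float
        Mass conversion g m⁻² → kg ha⁻¹ (×10).  Set to 1.0 if fluxes are
        already in the target mass unit.

    Returns
    -------
    xarray.Dataset
        ``eco2``, ``en2o``, ``ech4``, ``eghg`` (kg CO₂-eq/ha) and ``ghgi``
        (kg CO₂-eq per kg grain, NaN-masked at near-zero yield).
    """
    eco2 = co2_to_co2eq(scenario["fco2"].values) * flux_to_kg_ha
    en2o = n2o_to_co2eq(scenario["fn2o"].values) * flux_to_kg_ha
    ech4 = ch4_to_co2eq(scenario["fch4"].values) * flux_to_kg_ha
    eghg = net_ghg(eco2, en2o, ech4)
    intensity = ghgi(eghg, scenario["yield"].values)
    dims = scenario["fco2"].dims
    out = xr.Dataset(
        {
            "eco2": (dims, eco2, {"units": "kg CO2-eq ha-1 yr-1"}),
            "en2o": (dims, en2o, {"units": "kg CO2-eq ha-1 yr-1"}),
            "ech4": (dims, ech4, {"units": "kg CO2-eq ha-1 yr-1"}),
            "eghg": (dims, eghg, {"units": "kg CO2-eq ha-1 yr-1"}),
            "ghgi": (dims, intensity, {"units": "kg CO2-eq (kg grain)-1"}),
        },
        coords=scenario.coords,
        attrs=dict(scenario.attrs),
    )
    return out


def cell_areas_km2(lat, lon) -> np.ndarray:
    """Spherical cell areas (km²) for a regular lat/lon grid of cell centers."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    r_earth = 6371.0
    dlat = np.deg2rad(np.abs(lat[1] - lat[0])) if lat.size > 1 else np.deg2rad(1.0)
    dlon = np.deg2rad(np.abs(lon[1] - lon[0])) if lon.size > 1 else np.deg2rad(1.0)
    band = r_earth**2 * dlon * dlat * np.cos(np.deg2rad(lat))
    return np.repeat(band[:, None], lon.size, axis=1)


_RESPONSE_VARS = ("yield", "fco2", "fn2o", "fch4")


def _check_aligned(a: xr.Dataset, b: xr.Dataset) -> None:
    for c in ("lat", "lon", "year"):
        if not np.array_equal(a[c].values, b[c].values):
            raise ValueError(f"scenario grids differ on coordinate '{c}'")


def attribute_factor(s2: xr.Dataset, s_without: xr.Dataset, factor: str,
                     wheat_fraction=None) -> xr.Dataset:
    """Contribution of one driver: all-drivers run minus run without it.

    Returns the per-cell/year contribution for every response variable,
    plus area-weighted regional totals (``<var>_total``) using spherical
    cell areas times an optional wheat-fraction layer (default 1).
    """
    _check_aligned(s2, s_without)
    areas = cell_areas_km2(s2["lat"].values, s2["lon"].values)
    if wheat_fraction is not None:
        areas = areas * np.asarray(wheat_fraction, dtype=float)
    data = {}
    for v in _RESPONSE_VARS:
        diff = s2[v].values - s_without[v].values
        data[v] = (("lat", "lon", "year"), diff)
        data[v + "_total"] = (("year",), np.tensordot(areas, diff, axes=([0, 1], [0, 1])))
    out = xr.Dataset(data, coords={"lat": s2["lat"], "lon": s2["lon"], "year": s2["year"]})
    out.attrs["factor"] = factor
    out.attrs["area_weighting"] = "spherical cell area x wheat fraction (default 1)"
    return out


def attribute_lulc(s10: xr.Dataset, s11: xr.Dataset, wheat_fraction=None) -> xr.Dataset:
    """Land-use/land-cover contribution from the management-frozen pair."""
    return attribute_factor(s10, s11, factor="LULC", wheat_fraction=wheat_fraction)


def fit_metrics(obs, sim) -> dict:
    """Model-evaluation metrics: R², RMSE and normalized RMSE.

    R² is the coefficient of determination of the OLS regression of
    simulated on observed values; nRMSE = RMSE / mean(obs).
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("obs and sim must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(obs) == 0:
        raise ValueError("R^2 undefined for zero-variance observations")
    r = np.corrcoef(obs, sim)[0, 1]
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    mean_obs = float(np.mean(obs))
    if mean_obs == 0:
        raise ValueError("nRMSE undefined when mean(obs) = 0")
    return {"r2": float(r * r), "rmse": rmse, "nrmse": rmse / mean_obs}
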