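"""Synthetic gridded climate and factorial scenario outputs.

This module emulates what a process-based agroecosystem model driven by
historical data would hand to the analysis: daily gridded climate with a
seasonal cycle, warming and drying trends, and annual yield/GHG-flux
fields for a factorial experiment suite (S1–S13) in which every
driver-response coupling is *injected with known sign and magnitude*, so
each downstream stage has a ground-truth recovery test.

Scenario design
---------------
S1 holds every driver at its baseline (no trends, no dry-heat coupling);
S2 activates all drivers ("actual"); S3–S9 each deactivate exactly one of
{climate, CO2, Ndep, LULC, Nfer, manure, irrigation}; S10/S11 freeze
management and differ only in land cover (their difference isolates LULC);
S12/S13 are the all-driver run with no-till / conventional-till beta
multipliers applied in their configured regions.

Randomness
----------
All draws come from named child streams of the master seed
(``SeedSequence(seed, spawn_key=(crc32(name),))``).  Climate noise has its
own streams; response noise is keyed per *variable* and therefore shared
across scenarios — the emulated process model is deterministic, so
factorial runs differ only through driver settings, never through
internal randomness.  This is what makes paired scenario differences
(attribution, tillage effects) exact.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from . import indices

__all__ = [
    "SyntheticConfig",
    "TillageRegion",
    "SCENARIOS",
    "DRIVERS",
    "FACTOR_SCENARIO",
    "generate_daily_climate",
    "generate_scenario_outputs",
    "generate_scenario_suite",
]

DRIVERS = ("climate", "co2", "ndep", "lulc", "nfer", "manure", "irrigation")

#: Driver deactivated by each all-minus-one experiment.
FACTOR_SCENARIO = {
    "climate": "S3", "co2": "S4", "ndep": "S5", "lulc": "S6",
    "nfer": "S7", "manure": "S8", "irrigation": "S9",
}

_ALL = frozenset(DRIVERS)
SCENARIOS = {
    "S1": frozenset(),
    "S2": _ALL,
    **{s: _ALL - {d} for d, s in FACTOR_SCENARIO.items()},
    "S10": frozenset({"climate", "co2", "ndep", "lulc"}),
    "S11": frozenset({"climate", "co2", "ndep"}),
    "S12": _ALL,
    "S13": _ALL,
}

#: Deterministic driver trends, per decade, added when the driver is active.
#: Signs: fertilization and deposition raise yield and N2O; rising CO2
#: raises yield and sequesters carbon; land-use change expands cultivated
#: area (SOC loss); irrigation aids yield and wets soils (CH4).
DRIVER_RATES = {
    "co2": {"yield": 60.0, "fco2": -0.5},
    "ndep": {"yield": 15.0, "fn2o": 0.003},
    "lulc": {"yield": 30.0, "fco2": 0.6, "fn2o": 0.002},
    "nfer": {"yield": 150.0, "fco2": 0.3, "fn2o": 0.012},
    "manure": {"yield": 20.0, "fco2": 0.2, "fn2o": 0.004},
    "irrigation": {"yield": 40.0, "fco2": -0.1, "fch4": 0.004},
}

RESPONSE_VARS = ("yield", "fco2", "fn2o", "fch4")


@dataclass(frozen=True)
class TillageRegion:
    """Rectangular grid region where a tillage scenario rescales couplings.

    ``beta_scale`` multiplies every dry-heat beta inside the region
    (< 1 weakens the coupling, i.e. the practice buffers dry-heat impacts);
    cells outside keep the actual-scenario couplings unchanged.
    """

    row0: int
    row1: int
    col0: int
    col1: int
    beta_scale: float

    def mask(self, n_lat: int, n_lon: int) -> np.ndarray:
        m = np.zeros((n_lat, n_lon), dtype=bool)
        m[self.row0 : self.row1, self.col0 : self.col1] = True
        return m


def _default_regions():
    # NT buffers the northern band, CT the southern band (20x20 default grid).
    return {
        "NT": TillageRegion(13, 20, 0, 20, beta_scale=0.3),
        "CT": TillageRegion(0, 7, 0, 20, beta_scale=0.3),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic suite.

    Defaults emulate a six-decade (1960–2018) mid-latitude wheat belt on a
    20×20 grid: ~0.3 °C/decade warming, a drying trend of +0.02 dry-day
    probability per decade, right-skewed wet-day rainfall, and dry-heat
    damage betas of order 1% of yield per extreme day.  Identical config +
    seed reproduces bit-identical outputs.
    """

    n_lat: int = 20
    n_lon: int = 20
    year_start: int = 1960
    year_end: int = 2018
    lat_range: tuple = (32.0, 48.0)
    lon_range: tuple = (-104.0, -96.0)

    # temperature model, degC
    base_tmax: float = 24.0
    lat_gradient: float = -0.5          # degC per degree latitude (north colder)
    seasonal_temp_amplitude: float = 12.0
    temp_trend: float = 0.3             # degC per decade
    diurnal_range_mean: float = 10.0
    diurnal_range_sd: float = 2.0
    noise_sd_climate: float = 2.5       # degC, daily iid

    # precipitation model
    precip_mean: float = 2.5            # mm/day long-run mean
    precip_dry_prob: float = 0.55       # probability of a zero-rain day
    drying_trend: float = 0.02          # dry-day probability per decade
    gamma_shape: float = 0.8            # wet-day amount shape

    # annual response baselines
    base_yield: float = 7000.0          # kg/ha
    base_fco2: float = 20.0             # g C m-2 yr-1 (positive = release)
    base_fn2o: float = 0.15             # g N m-2 yr-1
    base_fch4: float = 0.05             # g C m-2 yr-1

    # injected dry-heat couplings: response change per EDH day, balanced so
    # every index carries a comparable share of the response signal
    beta_yield: dict = field(default_factory=lambda: {"hc": -20.0, "dc": -10.5, "cdhc": -5.0})
    beta_ghg: dict = field(default_factory=lambda: {
        "fco2": {"hc": 0.20, "dc": 0.105, "cdhc": 0.05},
        "fn2o": {"hc": 0.00105, "dc": 0.00055, "cdhc": 0.00025},
        "fch4": {"hc": 0.0004, "dc": 0.0001, "cdhc": 0.0001},
    })

    # response noise, per variable (shared across scenarios; see module doc);
    # sized near the injected signal's interannual SD so tillage-induced
    # sensitivity differences are detectable but not trivial
    noise_sd_response: dict = field(default_factory=lambda: {
        "yield": 95.0, "fco2": 0.95, "fn2o": 0.005, "fch4": 0.002,
    })

    tillage_effect_regions: dict = field(default_factory=_default_regions)

    seed: int = 0

    def __post_init__(self):
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be at least 1x1")
        if self.year_end - self.year_start + 1 < 21:
            raise ValueError("year range must span at least 21 years "
                             "(two 20-year windows)")
        if not 0.0 <= self.precip_dry_prob <= 1.0:
            raise ValueError("precip_dry_prob must lie in [0, 1]")
        for name in ("seasonal_temp_amplitude", "noise_sd_climate",
                     "diurnal_range_sd", "precip_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v < 0 for v in self.noise_sd_response.values()):
            raise ValueError("response noise SDs must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def truth(self) -> dict:
        """Ground-truth record serialized next to generated outputs.

        Holds the injected betas, driver rates and tillage multipliers for
        recovery tests; analysis code paths never read it.
        """
        return {
            "beta_yield": dict(self.beta_yield),
            "beta_ghg": {k: dict(v) for k, v in self.beta_ghg.items()},
            "driver_rates": {k: dict(v) for k, v in DRIVER_RATES.items()},
            "noise_sd_response": dict(self.noise_sd_response),
            "tillage_effect_regions": {
                k: asdict(v) for k, v in self.tillage_effect_regions.items()
            },
        }


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the master seed (crc32 key-splitting)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def generate_daily_climate(config: SyntheticConfig) -> xr.Dataset:
    """Generate the daily Tmax/Tmin/precip grid.

    Temperature: latitude-graded mean + sinusoidal seasonal cycle peaking
    in mid-July + linear warming trend + iid Gaussian noise; Tmin is Tmax
    minus a positive diurnal range (|N(mean, sd²)|), so Tmax ≥ Tmin by
    construction.  Precipitation: mixed Bernoulli(dry)/Gamma(wet amount)
    with the dry-day probability drifting at ``drying_trend`` per decade.
    Real Gregorian calendar including leap days.
    """
    cfg = config
    dates = pd.date_range(f"{cfg.year_start}-01-01", f"{cfg.year_end}-12-31", freq="D")
    n_time = dates.size
    lat = np.linspace(cfg.lat_range[0], cfg.lat_range[1], cfg.n_lat)
    lon = np.linspace(cfg.lon_range[0], cfg.lon_range[1], cfg.n_lon)

    doy = dates.dayofyear.values.astype(float)
    # trend steps by calendar year so annual means are exactly linear in year
    decades = (dates.year.values - cfg.year_start) / 10.0
    seasonal = cfg.seasonal_temp_amplitude * np.cos(2.0 * np.pi * (doy - 197.0) / 365.25)
    lat_mid = 0.5 * (cfg.lat_range[0] + cfg.lat_range[1])
    lat_term = cfg.lat_gradient * (lat - lat_mid)

    shape = (cfg.n_lat, cfg.n_lon, n_time)
    noise = _rng(cfg.seed, "climate/tmax_noise").normal(0.0, 1.0, size=shape)
    tmax = (
        cfg.base_tmax
        + lat_term[:, None, None]
        + seasonal[None, None, :]
        + cfg.temp_trend * decades[None, None, :]
        + cfg.noise_sd_climate * noise
    )
    diurnal = np.abs(
        _rng(cfg.seed, "climate/diurnal").normal(
            cfg.diurnal_range_mean, cfg.diurnal_range_sd, size=shape
        )
    )
    tmin = tmax - diurnal

    dry_prob = np.clip(cfg.precip_dry_prob + cfg.drying_trend * decades, 0.0, 1.0)
    wet = _rng(cfg.seed, "climate/precip_occurrence").uniform(size=shape) >= dry_prob[None, None, :]
    wet_frac = max(1.0 - cfg.precip_dry_prob, 1e-9)
    scale = cfg.precip_mean / cfg.gamma_shape / wet_frac
    amount = _rng(cfg.seed, "climate/precip_amount").gamma(cfg.gamma_shape, scale, size=shape)
    precip = np.where(wet, amount, 0.0)

    return xr.Dataset(
        {
            "tmax": (("lat", "lon", "time"), tmax, {"units": "degC"}),
            "tmin": (("lat", "lon", "time"), tmin, {"units": "degC"}),
            "precip": (("lat", "lon", "time"), precip, {"units": "mm day-1"}),
        },
        coords={"lat": ("lat", lat, {"units": "degrees_north"}),
                "lon": ("lon", lon, {"units": "degrees_east"}),
                "time": dates},
        attrs={"seed": cfg.seed, "title": "synthetic daily climate"},
    )


def _beta_multiplier(cfg: SyntheticConfig, scenario: str) -> np.ndarray:
    mult = np.ones((cfg.n_lat, cfg.n_lon))
    practice = {"S12": "NT", "S13": "CT"}.get(scenario)
    if practice is not None and practice in cfg.tillage_effect_regions:
        region = cfg.tillage_effect_regions[practice]
        mult[region.mask(cfg.n_lat, cfg.n_lon)] = region.beta_scale
    return mult


def generate_scenario_outputs(
    edh: xr.Dataset, config: SyntheticConfig, scenario: str,
    wheat_type: str = "winter",
) -> xr.Dataset:
    """Annual yield and gas fluxes for one factorial experiment.

    Each response is baseline + active deterministic driver trends +
    (if the climate driver is active) the injected dry-heat coupling
    Σ_k beta_k·EDH_k — with betas rescaled by the tillage region
    multipliers in S12/S13 — + shared Gaussian noise.  Yield is floored at
    zero.  The injected truth is serialized into ``attrs["truth_json"]``.
    """
    cfg = config
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario '{scenario}'; expected S1..S13")
    if edh.sizes["lat"] != cfg.n_lat or edh.sizes["lon"] != cfg.n_lon:
        raise ValueError("EDH grid does not match the configuration grid")
    years = edh["year"].values
    if not np.array_equal(years, cfg.years):
        raise ValueError("EDH years do not match the configuration years")

    active = SCENARIOS[scenario]
    decades = (years - cfg.year_start) / 10.0
    mult = _beta_multiplier(cfg, scenario)

    edh_arrays = {k: edh[k].transpose("lat", "lon", "year").values.astype(float)
                  for k in ("hc", "dc", "cdhc")}
    betas = {"yield": cfg.beta_yield, **cfg.beta_ghg}
    bases = {"yield": cfg.base_yield, "fco2": cfg.base_fco2,
             "fn2o": cfg.base_fn2o, "fch4": cfg.base_fch4}

    shape = (cfg.n_lat, cfg.n_lon, years.size)
    data = {}
    for var in RESPONSE_VARS:
        resp = np.full(shape, bases[var])
        for driver, rates in DRIVER_RATES.items():
            if driver in active and var in rates:
                resp = resp + rates[var] * decades[None, None, :]
        if "climate" in active:
            coupling = sum(betas[var][k] * edh_arrays[k] for k in ("hc", "dc", "cdhc"))
            resp = resp + mult[:, :, None] * coupling
        sd = cfg.noise_sd_response[var]
        # variable-keyed stream: identical residuals in every scenario
        noise = _rng(cfg.seed, f"response/{var}").normal(0.0, 1.0, size=shape)
        resp = resp + sd * noise
        if var == "yield":
            resp = np.maximum(resp, 0.0)
        data[var] = (("lat", "lon", "year"), resp)

    units = {"yield": "kg ha-1", "fco2": "g C m-2 yr-1",
             "fn2o": "g N m-2 yr-1", "fch4": "g C m-2 yr-1"}
    ds = xr.Dataset(
        {k: (dims, arr, {"units": units[k]}) for k, (dims, arr) in data.items()},
        coords={"lat": edh["lat"], "lon": edh["lon"], "year": years},
        attrs={
            "scenario": scenario,
            "wheat_type": wheat_type,
            "seed": cfg.seed,
            "truth_json": json.dumps({"scenario": scenario, **cfg.truth()}),
        },
    )
    return ds


def generate_scenario_suite(
    config: SyntheticConfig,
    scenarios=tuple(SCENARIOS),
    wheat_type: str = "winter",
    climate: xr.Dataset | None = None,
    edh: xr.Dataset | None = None,
):
    """Generate the full factorial suite.

    Returns ``(climate, edh, {scenario: ScenarioAnnualField})``.  Climate
    and EDH fields can be passed in to avoid recomputation.
    """
    if climate is None:
        climate = generate_daily_climate(config)
    if edh is None:
        edh = indices.compute_edh_field(climate)
    suite = {
        s: generate_scenario_outputs(edh, config, s, wheat_type=wheat_type)
        for s in scenarios
    }
    return climate, edh, suite
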