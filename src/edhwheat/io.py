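"""NetCDF / CSV serialization with schema checks.

Gridded data travel as CF-style NetCDF (dims ``lat``, ``lon`` and
``time``/``year``/``window_end_year``), written through xarray's scipy
backend (NetCDF3 classic).  Floats are stored as float32, integers as
int32; computation stays float64 in memory.  Scenario fields can also
round-trip through a long-format CSV (lat, lon, year, variable, value).
Every writer stamps the seed and package version into global attributes;
no timestamps, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .tillage import REC_CODES

__all__ = [
    "write_netcdf",
    "read_netcdf",
    "read_climate",
    "read_edh_field",
    "read_scenario",
    "scenario_to_csv",
    "scenario_from_csv",
    "recommendation_to_netcdf",
    "recommendation_from_netcdf",
]

_CLIMATE_VARS = ("tmax", "tmin", "precip")
_SCENARIO_VARS = ("yield", "fco2", "fn2o", "fch4")
_EDH_VARS = ("hc", "dc", "cdhc")


class SchemaError(ValueError):
    """A file is missing required variables or dimensions."""


def _sanitize_attrs(attrs: dict) -> dict:
    out = {}
    for k, v in attrs.items():
        if isinstance(v, bool):
            v = int(v)
        elif isinstance(v, (tuple, list)):
            v = ",".join(str(x) for x in v)
        elif not isinstance(v, (str, int, float, np.integer, np.floating)):
            v = str(v)
        out[k] = v
    return out


def write_netcdf(ds: xr.Dataset, path) -> None:
    """Write a dataset as NetCDF3 with float32/int32 payloads."""
    enc = ds.copy()
    enc.attrs = _sanitize_attrs(enc.attrs)
    for name, da in list(enc.data_vars.items()):
        if np.issubdtype(da.dtype, np.floating):
            enc[name] = da.astype(np.float32)
        elif np.issubdtype(da.dtype, np.integer) or da.dtype == bool:
            enc[name] = da.astype(np.int32)
        enc[name].attrs = _sanitize_attrs(da.attrs)
    for name in list(enc.coords):
        if np.issubdtype(enc[name].dtype, np.signedinteger):
            enc[name] = enc[name].astype(np.int32)
    enc.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    return ds.load()


def _require(ds: xr.Dataset, variables, dims, what: str) -> None:
    missing_v = [v for v in variables if v not in ds]
    missing_d = [d for d in dims if d not in ds.dims]
    if missing_v or missing_d:
        raise SchemaError(
            f"{what}: missing variables {missing_v or 'none'}, "
            f"missing dimensions {missing_d or 'none'}; "
            f"required variables are {list(variables)} on dims {list(dims)}"
        )


def read_climate(path) -> xr.Dataset:
    """Read a daily climate grid, enforcing the tmax/tmin/precip schema."""
    ds = read_netcdf(path)
    _require(ds, _CLIMATE_VARS, ("lat", "lon", "time"), "daily climate file")
    return ds


def read_edh_field(path) -> xr.Dataset:
    ds = read_netcdf(path)
    _require(ds, _EDH_VARS, ("lat", "lon", "year"), "EDH annual field file")
    return ds


def read_scenario(path) -> xr.Dataset:
    ds = read_netcdf(path)
    _require(ds, _SCENARIO_VARS, ("lat", "lon", "year"), "scenario annual field file")
    return ds


def scenario_to_csv(ds: xr.Dataset, path) -> None:
    """Long-format CSV: lat, lon, year, variable, value (one row per cell-year)."""
    frames = []
    for var in _SCENARIO_VARS:
        df = ds[var].to_dataframe(name="value").reset_index()
        df["variable"] = var
        frames.append(df[["lat", "lon", "year", "variable", "value"]])
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)


def scenario_from_csv(path, attrs: dict | None = None) -> xr.Dataset:
    """Rebuild a scenario field from the long-format CSV."""
    df = pd.read_csv(path)
    needed = {"lat", "lon", "year", "variable", "value"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"scenario CSV must have columns {sorted(needed)}")
    wide = df.pivot_table(index=["lat", "lon", "year"], columns="variable", values="value")
    missing = [v for v in _SCENARIO_VARS if v not in wide.columns]
    if missing:
        raise SchemaError(f"scenario CSV is missing variables {missing}")
    ds = xr.Dataset.from_dataframe(wide[list(_SCENARIO_VARS)])
    if attrs:
        ds.attrs.update(attrs)
    return ds


def recommendation_to_netcdf(rec: xr.Dataset, path) -> None:
    """Serialize a recommendation map, coding NT/CT/none as int8 1/2/0."""
    enc = {}
    for name, da in rec.data_vars.items():
        if da.dtype.kind in ("U", "O") and name.startswith("recommendation"):
            codes = np.vectorize(REC_CODES.get, otypes=[np.int8])(da.values)
            enc[name] = (da.dims, codes, {"codes": "0=none,1=NT,2=CT"})
        elif da.dtype == bool:
            enc[name] = (da.dims, da.values.astype(np.int8))
        else:
            enc[name] = (da.dims, da.values.astype(np.float32))
    out = xr.Dataset(enc, coords=rec.coords, attrs=_sanitize_attrs(rec.attrs))
    out.to_netcdf(path, engine="scipy")


def recommendation_from_netcdf(path) -> xr.Dataset:
    ds = read_netcdf(path)
    inv = {v: k for k, v in REC_CODES.items()}
    out = {}
    for name, da in ds.data_vars.items():
        if name.startswith("recommendation"):
            labels = np.vectorize(inv.get, otypes=[object])(da.values.astype(int))
            out[name] = (da.dims, labels.astype("U4"))
        elif name.startswith("full_mitigation"):
            out[name] = (da.dims, da.values.astype(bool))
        else:
            out[name] = (da.dims, da.values.astype(float))
    return xr.Dataset(out, coords=ds.coords, attrs=dict(ds.attrs))
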