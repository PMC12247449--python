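"""Environment-specific tillage recommendation from sensitivity differences.

For each grid cell and 20-year moving window, the effect of a tillage
counterfactual (NT = no-till, CT = conventional till) is the difference D
between the sensitivity (correlation R) under that scenario and under the
actual-management run.  Signs classify the effect:

    yield:  D > 0 → PE (positive effect),  D < 0 → NE
    GHG:    D > 0 → NE,                    D < 0 → PE
    GHGI:   D > 0 → NE,                    D < 0 → PE

i.e. a scenario helps when it strengthens the yield coupling or weakens
the emission/intensity coupling.  D = 0 windows are neutral and excluded
from both numerator and denominator of the positive-effect frequency.  A
cell is a *significant effect zone* for a scenario when its PE frequency
strictly exceeds 75% of labelled windows; the recommendation map keeps the
qualifying scenario (ties broken toward NT), and cells where neither
qualifies stay unmanaged ("none").
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .sensitivity import grid_sensitivity_trend

__all__ = [
    "effect_classify",
    "tillage_effect",
    "positive_effect_frequency",
    "recommend_tillage",
    "recommendation_map",
    "apply_recommendation",
    "sensitivity_reduction",
    "effect_trajectory",
    "REC_CODES",
]

#: Integer codes used on disk for the recommendation map.
REC_CODES = {"none": 0, "NT": 1, "CT": 2}

DEFAULT_THRESHOLD = 0.75

#: Variables where a positive sensitivity difference is beneficial.
_POSITIVE_GOOD = {"yield"}
_NEGATIVE_GOOD = {"GHG", "GHGI"}


def effect_classify(d_value, variable):
    """Classify a sensitivity difference as 'PE', 'NE' or 'neutral'.

    *variable* is one of ``yield``, ``GHG``, ``GHGI``.  Zero differences
    carry no information under the strict sign rules and return
    ``"neutral"``.
    """
    if variable in _POSITIVE_GOOD:
        good = d_value > 0
    elif variable in _NEGATIVE_GOOD:
        good = d_value < 0
    else:
        raise ValueError(f"unknown variable '{variable}'")
    if d_value == 0:
        return "neutral"
    return "PE" if good else "NE"


def tillage_effect(tillage_field: xr.Dataset, actual_field: xr.Dataset) -> xr.Dataset:
    """Per-cell, per-window sensitivity differences D = R_tillage − R_actual."""
    for c in ("lat", "lon", "window_end_year"):
        if not np.array_equal(tillage_field[c].values, actual_field[c].values):
            raise ValueError(f"sensitivity fields differ on coordinate '{c}'")
    out = {}
    for name in actual_field.data_vars:
        out[f"d_{name[2:]}"] = tillage_field[name] - actual_field[name]
    ds = xr.Dataset(out)
    ds.attrs["scenario"] = tillage_field.attrs.get("scenario", "tillage")
    ds.attrs["response"] = actual_field.attrs.get("response", "")
    return ds


def positive_effect_frequency(d_values, variable):
    """Fraction of non-neutral windows with a positive effect.

    NaN windows (undefined sensitivity) and exact zeros are excluded from
    numerator and denominator.  Returns NaN if no window carries a label.
    """
    d = np.asarray(d_values, dtype=float)
    if variable in _POSITIVE_GOOD:
        pe = d > 0
        ne = d < 0
    elif variable in _NEGATIVE_GOOD:
        pe = d < 0
        ne = d > 0
    else:
        raise ValueError(f"unknown variable '{variable}'")
    labelled = np.sum(pe) + np.sum(ne)
    if labelled == 0:
        return np.nan
    return float(np.sum(pe) / labelled)


def recommend_tillage(freq_nt, freq_ct, threshold=DEFAULT_THRESHOLD):
    """Pick the tillage practice for one cell from PE frequencies.

    A scenario qualifies when its frequency strictly exceeds *threshold*.
    If both qualify the higher frequency wins; an exact tie goes to NT
    (the lower-disturbance practice).  NaN frequencies never qualify.
    """
    nt = -np.inf if freq_nt is None or np.isnan(freq_nt) else freq_nt
    ct = -np.inf if freq_ct is None or np.isnan(freq_ct) else freq_ct
    nt_ok = nt > threshold
    ct_ok = ct > threshold
    if not nt_ok and not ct_ok:
        return "none"
    if nt_ok and not ct_ok:
        return "NT"
    if ct_ok and not nt_ok:
        return "CT"
    return "NT" if nt >= ct else "CT"


def recommendation_map(
    actual: xr.Dataset,
    nt: xr.Dataset,
    ct: xr.Dataset,
    variable: str = "GHGI",
    threshold: float = DEFAULT_THRESHOLD,
) -> xr.Dataset:
    """Build the per-cell, per-EDH-index tillage recommendation map.

    The decision variable defaults to GHGI (the mitigation target); yield
    and GHG maps can be produced as diagnostics by passing ``variable``.
    Returns the categorical recommendation (string array), NT/CT PE
    frequencies, and a full-mitigation flag (PE in every labelled window
    with none missing).
    """
    d_nt = tillage_effect(nt, actual)
    d_ct = tillage_effect(ct, actual)
    out = {}
    for key in ("hc", "dc", "cdhc"):
        dn = d_nt[f"d_{key}"].transpose("lat", "lon", "window_end_year").values
        dc_ = d_ct[f"d_{key}"].transpose("lat", "lon", "window_end_year").values
        shape = dn.shape[:2]
        freq_nt = np.full(shape, np.nan)
        freq_ct = np.full(shape, np.nan)
        rec = np.empty(shape, dtype=object)
        full = np.zeros(shape, dtype=bool)
        for i in range(shape[0]):
            for j in range(shape[1]):
                fn = positive_effect_frequency(dn[i, j], variable)
                fc = positive_effect_frequency(dc_[i, j], variable)
                freq_nt[i, j], freq_ct[i, j] = fn, fc
                choice = recommend_tillage(fn, fc, threshold)
                rec[i, j] = choice
                if choice == "NT":
                    full[i, j] = fn == 1.0
                elif choice == "CT":
                    full[i, j] = fc == 1.0
        out[f"recommendation_{key}"] = (("lat", "lon"), rec.astype("U4"))
        out[f"freq_nt_{key}"] = (("lat", "lon"), freq_nt)
        out[f"freq_ct_{key}"] = (("lat", "lon"), freq_ct)
        out[f"full_mitigation_{key}"] = (("lat", "lon"), full)

    # consensus: majority across the three indices, "none" on no majority
    recs = np.stack([out[f"recommendation_{k}"][1] for k in ("hc", "dc", "cdhc")])
    consensus = np.empty(recs.shape[1:], dtype=object)
    for i in range(recs.shape[1]):
        for j in range(recs.shape[2]):
            vals, counts = np.unique(recs[:, i, j], return_counts=True)
            best = vals[np.argmax(counts)]
            consensus[i, j] = best if counts.max() >= 2 else "none"
    out["recommendation_consensus"] = (("lat", "lon"), consensus.astype("U4"))

    ds = xr.Dataset(out, coords={"lat": actual["lat"], "lon": actual["lon"]})
    ds.attrs["decision_variable"] = variable
    ds.attrs["threshold"] = threshold
    return ds


def apply_recommendation(
    actual: xr.Dataset, nt: xr.Dataset, ct: xr.Dataset, rec_map: xr.Dataset
) -> xr.Dataset:
    """Splice the recommended scenario's R series into the actual field.

    Cellwise: recommended NT cells take the NT sensitivity series, CT cells
    the CT series, and "none" cells keep the actual series.  Idempotent by
    construction.
    """
    out = {}
    for key in ("hc", "dc", "cdhc"):
        rec = rec_map[f"recommendation_{key}"].values
        a = actual[f"r_{key}"].transpose("lat", "lon", "window_end_year").values
        n_ = nt[f"r_{key}"].transpose("lat", "lon", "window_end_year").values
        c_ = ct[f"r_{key}"].transpose("lat", "lon", "window_end_year").values
        res = np.where((rec == "NT")[..., None], n_, np.where((rec == "CT")[..., None], c_, a))
        out[f"r_{key}"] = (("lat", "lon", "window_end_year"), res)
    ds = xr.Dataset(out, coords={"lat": actual["lat"], "lon": actual["lon"],
                                 "window_end_year": actual["window_end_year"]},
                    attrs=dict(actual.attrs))
    ds.attrs["tillage_scheme"] = "environment-specific (recommended map applied)"
    return ds


def sensitivity_reduction(
    actual: xr.Dataset, optimal: xr.Dataset, mask
) -> dict:
    """Percent reduction in regional sensitivity under the optimal scheme.

    For each EDH index, per window: the spatial median of R over the
    recommended (masked) cells under the actual and optimal fields; the
    per-window relative change 100·(median_actual − median_optimal)/
    |median_actual| is then averaged over windows.  Windows where the
    actual median's magnitude is below 1e-6 are undefined and skipped.

    Returns per-index percentages plus their mean and (min, max) range
    across the three indices.
    """
    mask = np.asarray(mask, dtype=bool)
    per_index = {}
    for key in ("hc", "dc", "cdhc"):
        a = actual[f"r_{key}"].transpose("lat", "lon", "window_end_year").values[mask]
        o = optimal[f"r_{key}"].transpose("lat", "lon", "window_end_year").values[mask]
        if a.size == 0:
            per_index[key] = np.nan
            continue
        med_a = np.nanmedian(a, axis=0)
        med_o = np.nanmedian(o, axis=0)
        ok = np.abs(med_a) >= 1e-6
        if not ok.any():
            per_index[key] = np.nan
            continue
        rel = 100.0 * (med_a[ok] - med_o[ok]) / np.abs(med_a[ok])
        per_index[key] = float(np.mean(rel))
    vals = [v for v in per_index.values() if not np.isnan(v)]
    summary = {
        "per_index": per_index,
        "mean": float(np.mean(vals)) if vals else np.nan,
        "range": (float(np.min(vals)), float(np.max(vals))) if vals else (np.nan, np.nan),
    }
    return summary


def effect_trajectory(d_field: xr.Dataset, variable: str = "GHGI") -> xr.Dataset:
    """Trend of tillage-effect magnitude D over window end-years.

    Per cell and EDH index: OLS slope and p-value of D on end-year, plus
    the cell's current status (PE/NE/neutral from the final window) so
    deteriorating negative effects and fading positive effects can be told
    apart.
    """
    end_years = d_field["window_end_year"].values.astype(float)
    out = {}
    for key in ("hc", "dc", "cdhc"):
        d = d_field[f"d_{key}"].transpose("lat", "lon", "window_end_year").values
        shape = d.shape[:2]
        slope = np.full(shape, np.nan)
        pval = np.full(shape, np.nan)
        status = np.empty(shape, dtype=object)
        for i in range(shape[0]):
            for j in range(shape[1]):
                tr = grid_sensitivity_trend(d[i, j], end_years)
                slope[i, j], pval[i, j] = tr["slope"], tr["p_value"]
                last = d[i, j][~np.isnan(d[i, j])]
                status[i, j] = (
                    effect_classify(float(last[-1]), variable) if last.size else "neutral"
                )
        out[f"d_{key}_slope"] = (("lat", "lon"), slope)
        out[f"d_{key}_p"] = (("lat", "lon"), pval)
        out[f"d_{key}_status"] = (("lat", "lon"), status.astype("U8"))
    return xr.Dataset(out, coords={"lat": d_field["lat"], "lon": d_field["lon"]},
                      attrs={"variable": variable})
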