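"""Moving-window sensitivity of annual responses to dry-heat indices.

"Sensitivity" is the correlation coefficient R between an annual EDH index
(HC, DC or CDHC) and an annual response (yield, net GHG, or GHGI) within a
20-year moving window, after both series are linearly detrended over the
full study period.  The sign of R gives the direction of the coupling, its
magnitude the strength.  Temporal change in sensitivity is summarized per
grid cell by an OLS trend of R on window end-year (two-sided t-test), and
regionally by the Mann–Kendall rank test, which needs no normality
assumption.  Uncertainty across climate-dataset × correlation-method
combinations is the standard error SE = s/√n.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy import stats

__all__ = [
    "detrend_linear",
    "moving_window_correlation",
    "sensitivity_field",
    "grid_sensitivity_trend",
    "grid_trend_field",
    "mann_kendall_trend",
    "uncertainty_across_combinations",
    "regional_summary",
    "TrendResult",
]

METHODS = ("pearson", "kendall", "spearman")
DEFAULT_WINDOW = 20
ALPHA = 0.05


def detrend_linear(series, axis=-1):
    """Remove the OLS linear trend along *axis*; residuals have zero mean
    and zero slope.  NaNs propagate through the whole slice."""
    y = np.asarray(series, dtype=float)
    n = y.shape[axis]
    if n < 3:
        raise ValueError("need at least 3 points to detrend")
    t = np.arange(n, dtype=float)
    y = np.moveaxis(y, axis, -1)
    tc = t - t.mean()
    denom = np.sum(tc**2)
    slope = (y @ tc) / denom
    resid = y - y.mean(axis=-1, keepdims=True) - slope[..., None] * tc
    return np.moveaxis(resid, -1, axis)


def _corr(x, y, method):
    if method == "pearson":
        sx = x - x.mean()
        sy = y - y.mean()
        denom = np.sqrt((sx @ sx) * (sy @ sy))
        if denom == 0:
            return np.nan
        return float((sx @ sy) / denom)
    if method == "kendall":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan
        return float(stats.kendalltau(x, y).statistic)
    if method == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method '{method}'; expected one of {METHODS}")


def moving_window_correlation(x, y, window=DEFAULT_WINDOW, method="pearson"):
    """Correlation of two annual series in trailing windows.

    For each end index e ≥ window−1, R is computed over the slice
    [e−window+1, e].  R is NaN where either series is constant within the
    window or contains missing values.

    Returns an array of length ``len(x) − window + 1`` (one value per
    window end year).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if window < 3:
        raise ValueError("window must be at least 3 years")
    if window > x.size:
        raise ValueError("window longer than the series")
    n_win = x.size - window + 1
    out = np.full(n_win, np.nan)
    for i in range(n_win):
        xs = x[i : i + window]
        ys = y[i : i + window]
        if np.any(np.isnan(xs)) or np.any(np.isnan(ys)):
            continue
        out[i] = _corr(xs, ys, method)
    return out


def _pearson_windows_grid(x, y, window):
    """Vectorized trailing-window Pearson R for (cells..., years) arrays."""
    n = x.shape[-1]
    n_win = n - window + 1
    sh = x.shape[:-1] + (n_win,)
    bad = np.isnan(x) | np.isnan(y)
    xz = np.where(bad, 0.0, x)
    yz = np.where(bad, 0.0, y)

    def wsum(a):
        c = np.concatenate([np.zeros(a.shape[:-1] + (1,)), np.cumsum(a, axis=-1)], axis=-1)
        return c[..., window:] - c[..., :-window]

    nbad = wsum(bad.astype(float))
    sx, sy = wsum(xz), wsum(yz)
    sxx, syy, sxy = wsum(xz * xz), wsum(yz * yz), wsum(xz * yz)
    w = float(window)
    cov = sxy - sx * sy / w
    vx = sxx - sx * sx / w
    vy = syy - sy * sy / w
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    r = np.where((nbad > 0) | (vx <= 0) | (vy <= 0), np.nan, r)
    assert r.shape == sh
    return r


def sensitivity_field(
    edh: xr.Dataset,
    response: xr.DataArray,
    window: int = DEFAULT_WINDOW,
    method: str = "pearson",
    detrend: str = "full",
    dataset_variant: str = "default",
) -> xr.Dataset:
    """Per-cell moving-window sensitivity of a response to HC/DC/CDHC.

    Both the index and the response series are linearly detrended over the
    full period (``detrend="full"``, the default) or within each window
    (``detrend="window"``) before correlating.  Cells/years with missing
    response values yield NaN in every window that touches them.

    Returns a Dataset with one variable per EDH index (``r_hc``, ``r_dc``,
    ``r_cdhc``) on dims ``(lat, lon, window_end_year)``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if detrend not in ("full", "window"):
        raise ValueError("detrend must be 'full' or 'window'")
    years = edh["year"].values
    if not np.array_equal(years, response["year"].values):
        raise ValueError("EDH and response year coordinates differ")
    n = years.size
    if window > n:
        raise ValueError("window longer than the record")
    resp = response.transpose("lat", "lon", "year").values.astype(float)

    def prep(a):
        if detrend == "full":
            full_nan = np.isnan(a).any(axis=-1)
            out = np.where(np.isnan(a), np.nan, a)
            ok = ~full_nan
            res = np.array(a, dtype=float)
            if ok.any():
                res[ok] = detrend_linear(a[ok], axis=-1)
            res[~ok] = np.nan
            return res
        return a  # per-window detrending happens inside the correlation

    data = {}
    end_years = years[window - 1 :]
    for key in ("hc", "dc", "cdhc"):
        x = edh[key].transpose("lat", "lon", "year").values.astype(float)
        if detrend == "full":
            xd, yd = prep(x), prep(resp)
        else:
            xd, yd = x, resp
        if method == "pearson" and detrend == "full":
            r = _pearson_windows_grid(xd, yd, window)
        else:
            r = np.full(x.shape[:2] + (n - window + 1,), np.nan)
            for i in range(x.shape[0]):
                for j in range(x.shape[1]):
                    for e in range(n - window + 1):
                        xs = xd[i, j, e : e + window]
                        ys = yd[i, j, e : e + window]
                        if np.any(np.isnan(xs)) or np.any(np.isnan(ys)):
                            continue
                        if detrend == "window":
                            xs = detrend_linear(xs)
                            ys = detrend_linear(ys)
                        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                            continue
                        r[i, j, e] = _corr(xs, ys, method)
        data[f"r_{key}"] = (("lat", "lon", "window_end_year"), r)

    out = xr.Dataset(
        data,
        coords={"lat": edh["lat"], "lon": edh["lon"], "window_end_year": end_years},
        attrs={
            "method": method,
            "window_length": window,
            "detrend": detrend,
            "dataset_variant": dataset_variant,
            "response": str(response.name or "response"),
        },
    )
    return out


class TrendResult(dict):
    """Mapping with ``slope``, ``p_value``, ``method`` and ``significant``."""

    @property
    def slope(self):
        return self["slope"]

    @property
    def p_value(self):
        return self["p_value"]

    @property
    def significant(self):
        return self["significant"]


def grid_sensitivity_trend(r_series, end_years=None, alpha=ALPHA) -> TrendResult:
    """OLS trend of a per-cell R series on window end-year.

    Constant series get slope 0 with p = 1 (no evidence of trend).
    """
    r = np.asarray(r_series, dtype=float)
    ok = ~np.isnan(r)
    t = np.arange(r.size, dtype=float) if end_years is None else np.asarray(end_years, dtype=float)
    r, t = r[ok], t[ok]
    if r.size < 3:
        return TrendResult(slope=np.nan, p_value=np.nan, method="ols", significant=False)
    if np.ptp(r) == 0:
        return TrendResult(slope=0.0, p_value=1.0, method="ols", significant=False)
    fit = stats.linregress(t, r)
    p = float(fit.pvalue)
    return TrendResult(slope=float(fit.slope), p_value=p, method="ols", significant=bool(p < alpha))


def grid_trend_field(field: xr.Dataset, alpha=ALPHA) -> xr.Dataset:
    """Apply :func:`grid_sensitivity_trend` to every cell of a sensitivity field."""
    end_years = field["window_end_year"].values.astype(float)
    out = {}
    for name, da in field.data_vars.items():
        arr = da.transpose("lat", "lon", "window_end_year").values
        slope = np.full(arr.shape[:2], np.nan)
        pval = np.full(arr.shape[:2], np.nan)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                tr = grid_sensitivity_trend(arr[i, j], end_years, alpha=alpha)
                slope[i, j], pval[i, j] = tr["slope"], tr["p_value"]
        out[f"{name}_slope"] = (("lat", "lon"), slope)
        out[f"{name}_p"] = (("lat", "lon"), pval)
    return xr.Dataset(out, coords={"lat": field["lat"], "lon": field["lon"]},
                      attrs={"alpha": alpha, "trend_method": "ols"})


def mann_kendall_trend(series, alpha=ALPHA) -> TrendResult:
    """Mann–Kendall rank test for a monotone trend.

    S = Σ_{i<j} sign(x_j − x_i); Var(S) carries the tie correction
    Σ t(t−1)(2t+5)/18, and the normal approximation uses the ±1 continuity
    correction.  The reported slope is the Theil–Sen median of pairwise
    slopes.  Two-sided p-value.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise ValueError("Mann-Kendall test needs at least 3 values")
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.sum(np.triu(diff, k=1)))
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    ii, jj = np.triu_indices(n, k=1)
    dt = (jj - ii).astype(float)
    sen = float(np.median((x[jj] - x[ii]) / dt))
    return TrendResult(slope=sen, p_value=p, method="mann_kendall",
                       significant=bool(p < alpha), s_statistic=s, z=float(z))


def uncertainty_across_combinations(fields) -> xr.Dataset:
    """Mean, standard deviation and SE = s/√n across dataset×method results.

    *fields* is a sequence of sensitivity Datasets on identical grids (one
    per climate-dataset × correlation-method combination; the full design
    is 3 × 3 = 9).  s uses ddof = 1.
    """
    fields = list(fields)
    if len(fields) < 2:
        raise ValueError("need at least 2 sensitivity fields")
    n = len(fields)
    out = {}
    ref = fields[0]
    for name in ref.data_vars:
        stack = np.stack([f[name].values for f in fields], axis=0)
        mean = np.nanmean(stack, axis=0)
        s = np.nanstd(stack, axis=0, ddof=1)
        out[f"{name}_mean"] = (ref[name].dims, mean)
        out[f"{name}_sd"] = (ref[name].dims, s)
        out[f"{name}_se"] = (ref[name].dims, s / np.sqrt(n))
    return xr.Dataset(out, coords=ref.coords, attrs={"n_combinations": n})


def regional_summary(field: xr.Dataset, mask=None) -> xr.Dataset:
    """Regional median R and signed-area shares per window.

    For each window end-year and EDH index: the spatial median of R over
    the (optionally masked) cells, and the fraction of valid cells with
    R > 0 and R < 0.  NaN cells are excluded from both median and shares.
    """
    out = {}
    for name, da in field.data_vars.items():
        arr = da.transpose("lat", "lon", "window_end_year").values
        if mask is not None:
            arr = arr[np.asarray(mask, dtype=bool)]
        else:
            arr = arr.reshape(-1, arr.shape[-1])
        med = np.nanmedian(arr, axis=0)
        valid = np.sum(~np.isnan(arr), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            pos = np.nansum(arr > 0, axis=0) / np.where(valid > 0, valid, np.nan)
            neg = np.nansum(arr < 0, axis=0) / np.where(valid > 0, valid, np.nan)
        out[f"{name}_median"] = (("window_end_year",), med)
        out[f"{name}_pos_share"] = (("window_end_year",), pos)
        out[f"{name}_neg_share"] = (("window_end_year",), neg)
    return xr.Dataset(out, coords={"window_end_year": field["window_end_year"]})
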