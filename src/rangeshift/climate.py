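"""Climatologies, delta-change projection, isotherm latitudes, heatwave
anomalies.

Two climatological metrics are supported over any year window: the
annual mean and the minimum monthly mean (MiMM — the coldest calendar
month of the across-years monthly climatology; a proxy for the winter
thermal minimum).  Model fields are projected by delta change: the
model's own anomaly relative to a base window is added to the observed
base climatology, which cancels any static model bias exactly.  Isotherm
latitudes are extracted per longitude column as the poleward-most linear
interpolated crossing of the threshold, which matches how range edges
are read off a map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .datatypes import SSTGrid

METRICS = ("annual_mean", "MiMM")


@dataclass
class ClimatologyField:
    metric: str
    values: xr.DataArray  # dims (lat, lon)
    window: tuple

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")


@dataclass
class HeatwaveAnomaly:
    sst_anomaly: xr.DataArray
    u_anomaly: xr.DataArray | None
    v_anomaly: xr.DataArray | None
    season: tuple
    event_year: int
    baseline: tuple


def _window_slice(da: xr.DataArray, window: tuple) -> xr.DataArray:
    y0, y1 = window
    t = pd.DatetimeIndex(da.time.values)
    have = set(t.year)
    missing = [y for y in range(y0, y1 + 1) if y not in have]
    if missing:
        raise ValueError(f"window {window} not covered; missing years {missing}")
    return da.sel(time=(da["time.year"] >= y0) & (da["time.year"] <= y1))


def climatology(
    g: SSTGrid,
    window: tuple,
    metric: str = "annual_mean",
    min_month_fraction: float = 0.8,
) -> ClimatologyField:
    """Climatological field over ``window`` (inclusive years).

    ``annual_mean`` averages all months; ``MiMM`` takes the minimum over
    calendar months of the across-years mean of each month.  Cells with
    fewer than ``min_month_fraction`` of months present are masked.
    """
    sub = _window_slice(g.data, window)
    present = np.isfinite(sub).mean("time")
    if metric == "annual_mean":
        vals = sub.mean("time", skipna=True)
    elif metric == "MiMM":
        vals = sub.groupby("time.month").mean("time", skipna=True).min("month")
    else:
        raise ValueError(f"metric must be one of {METRICS}")
    vals = vals.where(present >= min_month_fraction)
    return ClimatologyField(metric=metric, values=vals, window=tuple(window))


def regrid_to(da: xr.DataArray, target: xr.DataArray) -> xr.DataArray:
    """Bilinear regrid onto the target's lat/lon grid (identity when the
    grids already match)."""
    if np.array_equal(da.lat.values, target.lat.values) and np.array_equal(
        da.lon.values, target.lon.values
    ):
        return da
    return da.interp(lat=target.lat, lon=target.lon, method="linear")


def delta_change_project(
    model: SSTGrid,
    observed_clim: ClimatologyField,
    windows: list,
    base: tuple = (2008, 2017),
    metric: str | None = None,
) -> xr.DataArray:
    """Delta-change-corrected fields for each target window.

    corrected(window) = observed_clim + (model(window) - model(base)),
    all for the same metric.  A static model bias cancels exactly; over
    the base window the corrected field equals the observed climatology.
    Returns a DataArray with a leading ``window`` coordinate labelled by
    each window's start year.
    """
    metric = observed_clim.metric if metric is None else metric
    if metric != observed_clim.metric:
        raise ValueError("metric does not match the observed climatology")
    base_clim = climatology(model, base, metric).values
    base_clim = regrid_to(base_clim, observed_clim.values)
    out = []
    for w in windows:
        mw = regrid_to(climatology(model, tuple(w), metric).values, observed_clim.values)
        out.append(observed_clim.values + (mw - base_clim))
    return xr.concat(out, dim=pd.Index([w[0] for w in windows], name="window"))


def ensemble_mean(members: list):
    """Cell-wise ensemble mean and min-max spread across member fields.

    Members must share grids (and the window coordinate when present).
    Returns (mean, spread_min, spread_max).
    """
    if not members:
        raise ValueError("ensemble needs at least one member")
    ref = members[0]
    for m in members[1:]:
        if m.shape != ref.shape:
            raise ValueError("ensemble members have mismatched shapes")
    stack = xr.concat(members, dim=pd.RangeIndex(len(members), name="member"))
    return stack.mean("member"), stack.min("member"), stack.max("member")


# ---------------------------------------------------------------------------
# isotherm extraction
# ---------------------------------------------------------------------------

def isotherm_latitude(
    field2d: xr.DataArray,
    threshold: float,
    hemisphere: str = "south",
) -> pd.Series:
    """Per-longitude latitude of the poleward-most threshold crossing.

    The crossing is located by linear interpolation between adjacent grid
    latitudes; columns that never cross are NaN.  Multiple disjoint
    crossings resolve to the poleward-most one.
    """
    lats = field2d.lat.values
    out = {}
    poleward_min = hemisphere == "south"
    for lon in field2d.lon.values:
        col = field2d.sel(lon=lon).values
        ok = np.isfinite(col)
        crossings = []
        idx = np.where(ok)[0]
        for a, b in zip(idx[:-1], idx[1:]):
            if b != a + 1:
                continue
            v0, v1 = col[a] - threshold, col[b] - threshold
            if v0 == 0:
                crossings.append(lats[a])
            elif v0 * v1 < 0:
                frac = v0 / (v0 - v1)
                crossings.append(lats[a] + frac * (lats[b] - lats[a]))
        if ok.any() and col[ok][-1] == threshold:
            crossings.append(lats[np.where(ok)[0][-1]])
        if not crossings:
            out[float(lon)] = np.nan
        else:
            out[float(lon)] = min(crossings) if poleward_min else max(crossings)
    s = pd.Series(out, name=f"isotherm_{threshold}C")
    s.index.name = "lon"
    return s


def decadal_isotherm_series(
    observed: SSTGrid,
    models: list,
    threshold: float,
    decades: list,
    metric: str = "annual_mean",
    base: tuple = (2008, 2017),
    hemisphere: str = "south",
    scenario: str = "",
) -> pd.DataFrame:
    """Decadal isotherm-latitude series from a delta-change ensemble.

    For each decade (y0, y0+9): the mean contour comes from the
    decadal-mean ensemble-mean field (ensemble mean first, contour
    second); the min-max range spans the yearly ensemble-mean contours
    within the decade.  Columns: decade, scenario, lon, mean_lat,
    min_lat, max_lat.
    """
    obs_clim = climatology(observed, base, metric)
    rows = []
    for y0 in decades:
        dec = (y0, y0 + 9)
        dec_fields = [delta_change_project(m, obs_clim, [dec], base, metric).isel(window=0)
                      for m in models]
        mean_field, _, _ = ensemble_mean(dec_fields)
        mean_lat = isotherm_latitude(mean_field, threshold, hemisphere)
        yearly = []
        for y in range(dec[0], dec[1] + 1):
            yf = [delta_change_project(m, obs_clim, [(y, y)], base, metric).isel(window=0)
                  for m in models]
            ymean, _, _ = ensemble_mean(yf)
            yearly.append(isotherm_latitude(ymean, threshold, hemisphere))
        ymat = pd.concat(yearly, axis=1)
        if mean_lat.isna().all():
            warnings.warn(f"threshold {threshold} C not crossed in decade {dec}")
        for lon in mean_lat.index:
            rows.append(
                {
                    "decade": y0,
                    "scenario": scenario,
                    "threshold": threshold,
                    "lon": lon,
                    "mean_lat": mean_lat[lon],
                    "min_lat": ymat.loc[lon].min(),
                    "max_lat": ymat.loc[lon].max(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heatwave anomalies
# ---------------------------------------------------------------------------

def _season_mean(da: xr.DataArray, year: int, season: tuple) -> xr.DataArray:
    sel = da.sel(time=(da["time.year"] == year) & da["time.month"].isin(list(season)))
    if sel.sizes["time"] != len(season):
        raise ValueError(f"missing months of season {season} in year {year}")
    return sel.mean("time")


def _season_climatology(da: xr.DataArray, baseline: tuple, season: tuple) -> xr.DataArray:
    sub = _window_slice(da, baseline)
    sel = sub.sel(time=sub["time.month"].isin(list(season)))
    return sel.mean("time")


def heatwave_anomaly(
    g: SSTGrid,
    currents: xr.Dataset | None = None,
    event: tuple = (2011, (1, 2, 3)),
    baseline: tuple = (1980, 2015),
) -> HeatwaveAnomaly:
    """Seasonal anomaly of the event year against the baseline-window
    climatology of the same season, applied identically to SST and to
    each current component."""
    year, season = event
    sst_anom = _season_mean(g.data, year, season) - _season_climatology(g.data, baseline, season)
    u_anom = v_anom = None
    if currents is not None:
        u_anom = _season_mean(currents["u"], year, season) - _season_climatology(
            currents["u"], baseline, season
        )
        v_anom = _season_mean(currents["v"], year, season) - _season_climatology(
            currents["v"], baseline, season
        )
    return HeatwaveAnomaly(
        sst_anomaly=sst_anom, u_anomaly=u_anom, v_anomaly=v_anom,
        season=tuple(season), event_year=year, baseline=tuple(baseline),
    )
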