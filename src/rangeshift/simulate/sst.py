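"""Synthetic monthly SST fields emulating an observed product plus a
multi-model scenario ensemble.

The deterministic backbone of every field is a meridional plane with a
seasonal cycle and a linear warming trend,

    T(lat, t) = T0 - g * |lat - lat_ref| + A * cos(2*pi*(month - peak)/12)
                + bias_model + trend_scenario * (t - t0)/10yr + noise,

optionally with a localized heatwave pulse added to one season of one
year.  Each pseudo-model differs from the observed field by a static bias
(which delta-change correction must cancel exactly) and by its scenario
trend.  All fields share one grid and one land mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .._utils import sub_rng
from ..datatypes import SSTGrid


@dataclass
class HeatwavePulse:
    year: int = 2011
    season: tuple = (1, 2, 3)  # JFM, austral summer
    amplitude: float = 3.0  # degrees C
    lat_band: tuple = (-32.0, -22.0)
    lon_band: tuple | None = None  # None = all longitudes


@dataclass
class SSTSimSpec:
    lat_range: tuple = (-45.0, -5.0)
    lon_range: tuple = (110.0, 114.0)
    grid_step: float = 1.0
    years: tuple = (1900, 2100)
    monthly_mean: float = 28.0  # degrees C at the reference (equatorward) latitude
    lat_ref: float | None = None  # defaults to the equatorward grid edge
    meridional_gradient: float = 0.45  # degrees C per degree latitude
    seasonal_amplitude: float = 2.5
    seasonal_peak_month: int = 2  # late austral summer
    scenario_trends: dict = field(
        default_factory=lambda: {"historical_GHG": 0.06, "RCP4.5": 0.2, "RCP8.5": 0.4}
    )  # degrees C per decade
    observed_trend: float = 0.06
    model_biases: list = field(
        default_factory=lambda: [-1.5, -1.0, -0.6, -0.3, -0.1, 0.0, 0.1, 0.3, 0.6, 1.0, 1.5]
    )
    noise_sd: float = 0.1
    heatwave: HeatwavePulse | None = None
    land_mask: np.ndarray | None = None  # True = land, shape (lat, lon)
    check_thresholds: tuple = (17.0, 20.0)
    seed: int | None = None


def _grid(spec: SSTSimSpec):
    lat = np.arange(spec.lat_range[0], spec.lat_range[1] + 1e-9, spec.grid_step)
    lon = np.arange(spec.lon_range[0], spec.lon_range[1] + 1e-9, spec.grid_step)
    time = pd.date_range(f"{spec.years[0]}-01-01", f"{spec.years[1]}-12-01", freq="MS")
    return lat, lon, time


def _deterministic(spec: SSTSimSpec, lat, lon, time, trend, bias):
    lat_ref = spec.lat_ref
    if lat_ref is None:
        lat_ref = lat[np.argmin(np.abs(lat))] if (lat >= 0).any() else lat.max()
    months = time.month.to_numpy()
    years_elapsed = (time.year.to_numpy() + (months - 1) / 12.0) - spec.years[0]
    seasonal = spec.seasonal_amplitude * np.cos(
        2 * np.pi * (months - spec.seasonal_peak_month) / 12.0
    )
    base = spec.monthly_mean - spec.meridional_gradient * np.abs(lat - lat_ref)
    t = (
        base[None, :, None]
        + seasonal[:, None, None]
        + (trend * years_elapsed / 10.0)[:, None, None]
        + bias
    )
    return np.broadcast_to(t, (len(time), len(lat), len(lon))).copy()


def _add_pulse(field_: np.ndarray, spec: SSTSimSpec, lat, lon, time, amplitude=None):
    hw = spec.heatwave
    amp = hw.amplitude if amplitude is None else amplitude
    tmask = (time.year == hw.year) & np.isin(time.month, hw.season)
    latmask = (lat >= hw.lat_band[0]) & (lat <= hw.lat_band[1])
    lonmask = (
        np.ones(len(lon), bool)
        if hw.lon_band is None
        else (lon >= hw.lon_band[0]) & (lon <= hw.lon_band[1])
    )
    field_[np.ix_(tmask, latmask, lonmask)] += amp
    return field_


def _to_grid(values, lat, lon, time, spec, provenance, scenario) -> SSTGrid:
    if spec.land_mask is not None:
        values = np.where(spec.land_mask[None, :, :], np.nan, values)
    da = xr.DataArray(
        values.astype(np.float32),
        coords={"time": time, "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"),
        name="sst",
        attrs={"units": "degC", "provenance": provenance, "scenario": scenario},
    )
    return SSTGrid(data=da, provenance=provenance, scenario=scenario)


def simulate_sst(spec: SSTSimSpec, scenarios: list | None = None) -> dict:
    """Return {("observed","observed"): grid, (model, scenario): grid, ...}.

    One pseudo-model per entry of ``model_biases``; each model is produced
    for every requested scenario with that scenario's linear trend.  A
    warning is raised when the deterministic annual-mean plane never
    crosses a configured isotherm threshold at the final decade.
    """
    lat, lon, time = _grid(spec)
    rng = sub_rng(spec.seed, "sst")
    scenarios = list(spec.scenario_trends) if scenarios is None else scenarios

    # isotherm coverage check on the noise-free annual-mean plane
    lat_ref = spec.lat_ref if spec.lat_ref is not None else lat.max()
    final_elapsed = spec.years[1] - spec.years[0]
    for thr in spec.check_thresholds or ():
        for scen in scenarios:
            trend = spec.scenario_trends[scen]
            profile = (
                spec.monthly_mean
                - spec.meridional_gradient * np.abs(lat - lat_ref)
                + trend * final_elapsed / 10.0
            )
            if not (profile.min() <= thr <= profile.max()):
                warnings.warn(
                    f"grid never crosses the {thr} C isotherm under {scen} "
                    f"by {spec.years[1]}"
                )

    out = {}
    obs = _deterministic(spec, lat, lon, time, spec.observed_trend, 0.0)
    if spec.noise_sd > 0:
        obs += rng.normal(0, spec.noise_sd, obs.shape)
    if spec.heatwave is not None:
        obs = _add_pulse(obs, spec, lat, lon, time)
    out[("observed", "observed")] = _to_grid(obs, lat, lon, time, spec, "observed", "observed")

    for m, bias in enumerate(spec.model_biases):
        name = f"model_{m + 1:02d}"
        for scen in scenarios:
            t = _deterministic(spec, lat, lon, time, spec.scenario_trends[scen], bias)
            if spec.noise_sd > 0:
                t += rng.normal(0, spec.noise_sd, t.shape)
            out[(name, scen)] = _to_grid(t, lat, lon, time, spec, name, scen)
    return out


def simulate_currents(
    spec: SSTSimSpec,
    u_mean: float = 0.1,
    v_mean: float = -0.3,
    pulse_amplitude: float = 0.4,
    noise_sd: float = 0.02,
) -> xr.Dataset:
    """Near-surface current components: steady flow plus a poleward pulse
    during the configured heatwave (added to the v component within the
    pulse footprint)."""
    lat, lon, time = _grid(spec)
    rng = sub_rng(spec.seed, "currents")
    shape = (len(time), len(lat), len(lon))
    u = np.full(shape, u_mean) + rng.normal(0, noise_sd, shape)
    v = np.full(shape, v_mean) + rng.normal(0, noise_sd, shape)
    if spec.heatwave is not None:
        v = _add_pulse(v, spec, lat, lon, time, amplitude=-abs(pulse_amplitude))
    coords = {"time": time, "lat": lat, "lon": lon}
    return xr.Dataset(
        {
            "u": xr.DataArray(u.astype(np.float32), coords=coords, dims=("time", "lat", "lon"),
                              attrs={"units": "m s-1"}),
            "v": xr.DataArray(v.astype(np.float32), coords=coords, dims=("time", "lat", "lon"),
                              attrs={"units": "m s-1"}),
        }
    )
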