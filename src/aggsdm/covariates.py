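"""Environmental predictor derivation and observation matching.

Derives the predictor set used by the aggregation models from raw gridded
fields — neighborhood standard deviations (mesoscale variability proxies),
wind-stress curl, total kinetic energy of surface currents, bathymetric
rugosity, and great-circle distances — and matches the full covariate
vector to labeled observations at the daily, single-cell level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0088

#: Covariate columns produced by :func:`match_covariates`, in model order.
COVARIATE_NAMES = [
    "sst",
    "ssh",
    "chla",
    "curl",
    "tke",
    "sst_sd",
    "ssh_sd",
    "depth",
    "rugosity",
    "dist_colony",
    "dist_shore",
]


def _window_cells(window_degrees: float, resolution: float) -> int:
    n = window_degrees / resolution
    k = int(round(n))
    if abs(n - k) > 1e-6 or k < 1:
        raise ValueError(
            f"window {window_degrees}° is not a whole number of "
            f"{resolution}° cells"
        )
    if k % 2 == 0:
        raise ValueError(f"window must span an odd number of cells, got {k}")
    return k


def neighborhood_sd(
    field: np.ndarray, window_degrees: float = 0.3, resolution: float = 0.1
) -> np.ndarray:
    """Sample SD of a 2-D field over a centered square window.

    Each cell receives the sample standard deviation (ddof=1) of the valid
    values inside the window centered on it. Edge cells use the available
    sub-window; NaN cells stay NaN and are excluded from neighbors'
    statistics.
    """
    k = _window_cells(window_degrees, resolution)
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be 2-D")
    h = k // 2
    valid = np.isfinite(field)
    # center on the global mean: SD is shift-invariant and this avoids
    # catastrophic cancellation in the sum-of-squares formula
    shift = np.nanmean(field) if valid.any() else 0.0
    x = np.where(valid, field - shift, 0.0)
    # running sums over the window via padded cumulative sums
    ones = valid.astype(float)

    def window_sum(a: np.ndarray) -> np.ndarray:
        p = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
        p[1:, 1:] = np.cumsum(np.cumsum(a, axis=0), axis=1)
        ny, nx = a.shape
        i0 = np.clip(np.arange(ny) - h, 0, None)
        i1 = np.clip(np.arange(ny) + h + 1, None, ny)
        j0 = np.clip(np.arange(nx) - h, 0, None)
        j1 = np.clip(np.arange(nx) + h + 1, None, nx)
        return (
            p[np.ix_(i1, j1)] - p[np.ix_(i0, j1)] - p[np.ix_(i1, j0)] + p[np.ix_(i0, j0)]
        )

    n = window_sum(ones)
    s = window_sum(x)
    s2 = window_sum(x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s * s / n) / (n - 1)
    var = np.where(n > 1, np.maximum(var, 0.0), 0.0)
    out = np.sqrt(var)
    out[~valid] = np.nan
    out[n < 1] = np.nan
    return out


def wind_stress_curl(
    taux: np.ndarray,
    tauy: np.ndarray,
    lats: np.ndarray,
    window_degrees: float = 0.5,
    resolution: float = 0.1,
) -> np.ndarray:
    """Curl of the wind stress, ∂τy/∂x − ∂τx/∂y, in N/m³.

    Centered finite differences with a stencil half-width equal to the
    window half-width (0.5° window → differences taken 2 cells either
    side). Zonal spacing is scaled by cos(latitude). Near domain edges
    the stencil is clipped to the available cells (one-sided at the
    boundary), so the derivative is defined everywhere and remains exact
    for linear fields.
    """
    k = _window_cells(window_degrees, resolution)
    h = k // 2
    taux = np.asarray(taux, dtype=float)
    tauy = np.asarray(tauy, dtype=float)
    if taux.shape != tauy.shape:
        raise ValueError("taux and tauy must share a shape")
    ny, nx = taux.shape
    deg_m = np.deg2rad(1.0) * EARTH_RADIUS_KM * 1000.0  # meters per degree
    j0 = np.clip(np.arange(nx) - h, 0, nx - 1)
    j1 = np.clip(np.arange(nx) + h, 0, nx - 1)
    i0 = np.clip(np.arange(ny) - h, 0, ny - 1)
    i1 = np.clip(np.arange(ny) + h, 0, ny - 1)
    coslat = np.cos(np.deg2rad(np.asarray(lats)))[:, None]
    dx = (j1 - j0)[None, :] * resolution * deg_m * coslat
    dy = ((i1 - i0) * resolution * deg_m)[:, None]
    dtauy_dx = (tauy[:, j1] - tauy[:, j0]) / dx
    dtaux_dy = (taux[i1, :] - taux[i0, :]) / dy
    return dtauy_dx - dtaux_dy


def total_kinetic_energy(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """TKE of surface currents, ½(u² + v²), in m²/s²."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must share a shape")
    return 0.5 * (u * u + v * v)


def great_circle_distance(p1, p2) -> float:
    """Haversine distance in km between (lon, lat) points, vectorized.

    Sphere radius 6371.0088 km.
    """
    lon1, lat1 = np.asarray(p1[0], float), np.asarray(p1[1], float)
    lon2, lat2 = np.asarray(p2[0], float), np.asarray(p2[1], float)
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = phi2 - phi1
    dlam = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def sst_anomaly(sst: xr.DataArray) -> xr.DataArray:
    """Per-cell deviation of SST from its day-of-year climatology."""
    doy = sst["time"].dt.dayofyear
    clim = sst.groupby(doy).mean("time")
    return (sst.groupby(doy) - clim).drop_vars("dayofyear", errors="ignore")


def derive_covariate_fields(env: xr.Dataset, resolution: float | None = None) -> xr.Dataset:
    """Expand raw fields into the full daily predictor set.

    Adds curl (from wind stress), tke (from currents), sst_sd / ssh_sd
    (0.3° neighborhood SDs), and rugosity (0.3° SD of depth) to the raw
    sst / ssh / chla / depth / distance fields.
    """
    if resolution is None:
        resolution = float(abs(env["lat"].values[1] - env["lat"].values[0]))
    lats = env["lat"].values
    nt = env.sizes["time"]

    def per_day(func, *names):
        out = np.empty((nt,) + env[names[0]].shape[1:])
        for t in range(nt):
            out[t] = func(*(env[n].values[t] for n in names))
        return out

    ds = xr.Dataset(coords=env.coords)
    for raw in ("sst", "ssh", "chla"):
        ds[raw] = env[raw]
    ds["curl"] = (
        ("time", "lat", "lon"),
        per_day(
            lambda tx, ty: wind_stress_curl(tx, ty, lats, resolution=resolution),
            "taux",
            "tauy",
        ),
    )
    ds["tke"] = (("time", "lat", "lon"), per_day(total_kinetic_energy, "u", "v"))
    ds["sst_sd"] = (
        ("time", "lat", "lon"),
        per_day(lambda f: neighborhood_sd(f, resolution=resolution), "sst"),
    )
    ds["ssh_sd"] = (
        ("time", "lat", "lon"),
        per_day(lambda f: neighborhood_sd(f, resolution=resolution), "ssh"),
    )
    ds["depth"] = env["depth"]
    ds["rugosity"] = (
        ("lat", "lon"),
        neighborhood_sd(env["depth"].values, resolution=resolution),
    )
    ds["dist_colony"] = env["dist_colony"]
    ds["dist_shore"] = env["dist_shore"]
    return ds


def match_covariates(obs: pd.DataFrame, env: xr.Dataset) -> tuple[pd.DataFrame, dict]:
    """Attach the covariate vector to each labeled observation row.

    Looks up every (cell, date) in the daily covariate fields; rows with
    any missing (NaN) covariate are dropped and counted in the returned
    report. Dates outside the field record raise.

    Returns
    -------
    (table, report)
        `table` is `obs` plus one column per entry of COVARIATE_NAMES;
        `report` counts rows dropped for missing covariates.
    """
    cov = env if "curl" in env else derive_covariate_fields(env)
    times = pd.DatetimeIndex(cov["time"].values)
    obs = obs.reset_index(drop=True)
    if len(obs) == 0:
        return obs.assign(**{c: [] for c in COVARIATE_NAMES}), {"dropped_missing": 0}
    dates = pd.DatetimeIndex(obs["date"])
    if dates.min() < times.min() or dates.max() > times.max():
        raise ValueError("observation date outside environmental record")
    t_idx = times.get_indexer(dates)
    if np.any(t_idx < 0):
        raise ValueError("observation date not present in environmental record")
    iy = obs["lat_idx"].to_numpy()
    jx = obs["lon_idx"].to_numpy()
    out = obs.copy()
    for name in COVARIATE_NAMES:
        arr = cov[name].values
        if arr.ndim == 3:
            out[name] = arr[t_idx, iy, jx]
        else:
            out[name] = arr[iy, jx]
    missing = out[COVARIATE_NAMES].isna().any(axis=1)
    report = {"dropped_missing": int(missing.sum())}
    return out.loc[~missing].reset_index(drop=True), report
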