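"""Synthetic seascape, survey, and species-count generator.

Emulates the statistical structure the aggregation analysis assumes, with
known ground truth so every downstream stage has a recovery test:

* daily gridded environmental fields (SST, SSH, currents, wind stress,
  chlorophyll a, plus static bathymetry and distances) built from smooth
  cross-shore gradients plus spatially autocorrelated mesoscale noise,
  with a shared interannual warm/cool mode shifting SST and SSH domain
  means year by year;
* survey effort as seeded cell-day visits with partial coverage,
  mimicking strip-transect coverage of an annual spring survey;
* per-species zero-inflated counts whose occurrence follows a logistic
  model of the local covariates (with an optional colony-distance decay
  for resident, central-place foraging species) and whose positive counts
  are heavy-tailed (rounded lognormal). A fraction of visits are "patch
  encounters" whose log-mean count is boosted; the patch probability
  responds to the interannual warm mode with a controllable sign, which
  inflates the upper decile of counts — the quantity labeled as an
  aggregation downstream — without moving the median.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .covariates import great_circle_distance
from .grid import GridSpec

#: First day of the simulated survey season (month, day).
SEASON_START = (4, 1)

#: Default breeding-colony position (lon, lat): Southeast Farallon Island.
DEFAULT_COLONY = (-123.003, 37.698)

#: Domain-mean shift per unit warm index. The interannual mode enters
#: through SST and SSH only; chlorophyll keeps its spatial structure
#: without a warm-mode loading, so a species' presence response and its
#: aggregation response to warm years can be decoupled by construction.
WARM_AMPLITUDE = {"sst": 0.9, "ssh": 0.04, "log_chla": 0.0}


@dataclass(frozen=True)
class ClimateForcing:
    """Interannual warm/cool mode: one anomaly value per simulated year.

    ``warm_index`` is dimensionless; positive means a warm, high-sea-level
    year. ``mask`` optionally restricts where the forcing is applied
    (boolean (lat, lon) array; None applies it everywhere).
    """

    warm_index: Mapping[int, float]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.array(list(self.warm_index.values()), dtype=float)
        if vals.size == 0 or not np.all(np.isfinite(vals)):
            raise ValueError("warm_index must be nonempty and finite")

    @classmethod
    def random(cls, years, seed: int, sd: float = 1.0) -> "ClimateForcing":
        rng = np.random.default_rng(seed)
        return cls({int(y): float(v) for y, v in zip(years, rng.normal(0, sd, len(years)))})


@dataclass
class SpeciesSimConfig:
    """Generative parameters for one simulated species.

    Presence follows logit(p) = intercept + Σ coef·(covariate − ref)
    − colony_decay_km·dist_colony. Positive counts are
    round(lognormal(count_log_mean, count_log_sd)) clipped to ≥ 1; patch
    encounters add ``patch_log_boost`` to the log-mean. Patch log-odds =
    logit(patch_base_prob) + Σ patch coef·(covariate − ref) +
    agg_forcing·warm_index, so ``agg_forcing`` controls the sign and
    strength of the species' aggregation response to warm years.
    """

    name: str = "synthetic_species"
    presence_intercept: float = 0.3
    presence_coefs: dict = field(
        default_factory=lambda: {"log_chla": 1.6, "dist_shore": -0.025}
    )
    colony_decay_km: float = 0.0  # per km; > 0 for resident species
    count_log_mean: float = 2.0
    count_log_sd: float = 0.6
    patch_base_prob: float = 0.07
    patch_log_boost: float = 3.0
    patch_coefs: dict = field(default_factory=lambda: {"log_chla": 1.4})
    agg_forcing: float = 1.2
    flying_fraction: float = 0.3
    covariate_refs: dict = field(
        default_factory=lambda: {"sst": 13.0, "ssh": 0.0, "log_chla": 0.7, "dist_shore": 60.0}
    )

    def __post_init__(self) -> None:
        coefs = list(self.presence_coefs.values()) + list(self.patch_coefs.values())
        if not np.all(np.isfinite(coefs + [self.agg_forcing])):
            raise ValueError("coefficients must be finite")
        if self.colony_decay_km < 0:
            raise ValueError("colony decay rate must be >= 0")


def _season_dates(year: int, days: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(year, *SEASON_START)
    return pd.date_range(start, periods=days, freq="D")


def _smooth_noise(rng, shape, sigma_cells: float, sd: float) -> np.ndarray:
    """Gaussian random field: smoothed white noise rescaled to target SD."""
    w = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    s = w.std()
    return w * (sd / s) if s > 0 else w


def generate_environment(
    grid: GridSpec,
    years,
    days_per_year: int,
    forcing: ClimateForcing,
    seed: int,
    noise_sd_sst: float = 0.25,
    noise_corr_cells: float = 3.0,
    colony: tuple[float, float] = DEFAULT_COLONY,
) -> xr.Dataset:
    """Generate daily environmental fields plus static bathymetry.

    Dynamic fields share (time, lat, lon); the time axis covers
    ``days_per_year`` days from April 1 of each year. SST and SSH domain
    means are shifted by the year's warm index (see WARM_AMPLITUDE);
    chlorophyll is log-normal, lower in warm years. Depth is reported as
    a positive magnitude (meters below the surface) increasing offshore;
    the eastern grid edge acts as the shore.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    if len(set(years)) != len(years):
        raise ValueError("duplicate years")
    missing = [y for y in years if y not in forcing.warm_index]
    if missing:
        raise ValueError(f"forcing missing years {missing}")
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape()
    lons, lats = grid.lons, grid.lats
    offshore = (grid.lon_max - lons)[None, :] / (grid.lon_max - grid.lon_min)
    offshore = np.broadcast_to(offshore, (ny, nx))

    # static fields
    depth = 25.0 + 3800.0 * offshore**1.6
    lon2, lat2 = np.meshgrid(lons, lats)
    dist_shore = great_circle_distance((lon2, lat2), (np.full_like(lon2, grid.lon_max), lat2))
    dist_colony = great_circle_distance(
        (lon2, lat2), (np.full_like(lon2, colony[0]), np.full_like(lat2, colony[1]))
    )

    mask = forcing.mask if forcing.mask is not None else np.ones((ny, nx))
    mask = np.asarray(mask, dtype=float)

    dates, wi_daily = [], []
    for y in years:
        d = _season_dates(y, days_per_year)
        dates.append(d)
        wi_daily.append(np.full(len(d), forcing.warm_index[y]))
    time = dates[0].append(dates[1:]) if len(dates) > 1 else dates[0]
    wi = np.concatenate(wi_daily)
    nt = len(time)

    def stack(base, warm_amp, sd, positive=False):
        out = np.empty((nt, ny, nx))
        for t in range(nt):
            out[t] = (
                base
                + warm_amp * wi[t] * mask
                + _smooth_noise(rng, (ny, nx), noise_corr_cells, sd)
            )
        return out

    sst = stack(12.5 + 1.8 * offshore, WARM_AMPLITUDE["sst"], noise_sd_sst)
    ssh = stack(-0.05 + 0.10 * offshore, WARM_AMPLITUDE["ssh"], 0.012)
    log_chla = stack(
        np.log(0.5) + 1.8 * (1.0 - offshore), WARM_AMPLITUDE["log_chla"], 0.70
    )
    u = stack(np.full((ny, nx), -0.02), 0.0, 0.08)
    v = stack(np.full((ny, nx), -0.06), 0.0, 0.08)
    taux = stack(np.full((ny, nx), 0.01), 0.0, 0.015)
    tauy = stack(np.full((ny, nx), -0.04), 0.0, 0.015)

    ds = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst),
            "ssh": (("time", "lat", "lon"), ssh),
            "u": (("time", "lat", "lon"), u),
            "v": (("time", "lat", "lon"), v),
            "taux": (("time", "lat", "lon"), taux),
            "tauy": (("time", "lat", "lon"), tauy),
            "chla": (("time", "lat", "lon"), np.exp(log_chla)),
            "depth": (("lat", "lon"), depth),
            "dist_shore": (("lat", "lon"), dist_shore),
            "dist_colony": (("lat", "lon"), dist_colony),
        },
        coords={"time": time, "lat": lats, "lon": lons},
        attrs={
            "depth_convention": "positive magnitude, meters below surface",
            "shore": "eastern grid edge",
        },
    )
    return ds


def generate_survey(
    grid: GridSpec,
    years,
    visits_per_year: int,
    seed: int,
    days_per_year: int = 91,
) -> pd.DataFrame:
    """Draw survey effort as cell-day visits with coverage fractions.

    Returns exactly ``visits_per_year`` rows per year: (year, date,
    lat_idx, lon_idx, coverage_fraction ∈ (0, 1]). Visits are uniform
    over cells and season days; coverage is uniform on (0, 1]. Repeat
    visits to a cell-day may occur (separate transects) and are combined
    at the gridding step.
    """
    if visits_per_year <= 0:
        raise ValueError("visits_per_year must be positive")
    ny, nx = grid.shape()
    if ny * nx == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    rows = []
    for y in sorted(years):
        d = _season_dates(y, days_per_year)
        day = rng.integers(0, days_per_year, visits_per_year)
        iy = rng.integers(0, ny, visits_per_year)
        jx = rng.integers(0, nx, visits_per_year)
        cov = 1.0 - rng.random(visits_per_year)  # (0, 1]
        rows.append(
            pd.DataFrame(
                {
                    "year": y,
                    "date": d[day],
                    "lat_idx": iy,
                    "lon_idx": jx,
                    "coverage_fraction": cov,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _linear_predictor(cfg_coefs, refs, values: dict) -> np.ndarray:
    lp = 0.0
    for name, coef in cfg_coefs.items():
        if name not in values:
            raise KeyError(f"covariate '{name}' named in config absent from fields")
        lp = lp + coef * (values[name] - refs.get(name, 0.0))
    return lp


def simulate_counts(
    env: xr.Dataset,
    effort: pd.DataFrame,
    cfg: SpeciesSimConfig,
    forcing: ClimateForcing,
    seed: int,
) -> pd.DataFrame:
    """Simulate a 3-km-bin sightings table over the survey effort.

    One record per effort visit: zero count where the presence draw
    fails, otherwise a positive integer count; each record carries a
    behavior label (flying / water / feeding) drawn independently of the
    count, and a position jittered inside its grid cell.
    """
    rng = np.random.default_rng(seed)
    times = pd.DatetimeIndex(env["time"].values)
    t_idx = times.get_indexer(pd.DatetimeIndex(effort["date"]))
    if np.any(t_idx < 0):
        raise ValueError("effort date missing from environment")
    iy = effort["lat_idx"].to_numpy()
    jx = effort["lon_idx"].to_numpy()
    values = {}
    for name in ("sst", "ssh", "chla"):
        values[name] = env[name].values[t_idx, iy, jx]
    values["log_chla"] = np.log(values["chla"])
    values["dist_colony"] = env["dist_colony"].values[iy, jx]
    values["dist_shore"] = env["dist_shore"].values[iy, jx]

    wi = np.array(
        [forcing.warm_index[int(y)] for y in pd.DatetimeIndex(effort["date"]).year]
    )
    lp = (
        cfg.presence_intercept
        + _linear_predictor(cfg.presence_coefs, cfg.covariate_refs, values)
        - cfg.colony_decay_km * values["dist_colony"]
    )
    p_presence = 1.0 / (1.0 + np.exp(-lp))
    present = rng.random(len(effort)) < p_presence

    patch_lp = (
        np.log(cfg.patch_base_prob / (1 - cfg.patch_base_prob))
        + _linear_predictor(cfg.patch_coefs, cfg.covariate_refs, values)
        + cfg.agg_forcing * wi
    )
    p_patch = 1.0 / (1.0 + np.exp(-patch_lp))
    patch = rng.random(len(effort)) < p_patch

    log_mu = cfg.count_log_mean + np.where(patch, cfg.patch_log_boost, 0.0)
    raw = np.exp(rng.normal(log_mu, cfg.count_log_sd))
    counts = np.where(present, np.maximum(1, np.round(raw)).astype(int), 0)

    u_beh = rng.random(len(effort))
    behavior = np.where(
        u_beh < cfg.flying_fraction,
        "flying",
        np.where(u_beh < cfg.flying_fraction + 0.7 * (1 - cfg.flying_fraction), "water", "feeding"),
    )

    res = env["lon"].values[1] - env["lon"].values[0] if env.sizes["lon"] > 1 else 0.1
    lon = env["lon"].values[jx] + rng.uniform(-0.45, 0.45, len(effort)) * res
    lat = env["lat"].values[iy] + rng.uniform(-0.45, 0.45, len(effort)) * res

    return pd.DataFrame(
        {
            "date": effort["date"].to_numpy(),
            "lon": lon,
            "lat": lat,
            "species": cfg.name,
            "count": counts,
            "behavior": behavior,
            "bin_id": np.arange(len(effort)),
        }
    )
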