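"""Independent evaluation of aggregation indices against observed fields.

Aggregation indices derived from the model hindcast are compared with
independently observed monthly SST and sea level anomaly (SLA) fields:

* SLA is SSH minus the long-term per-cell, per-calendar-month mean SSH
  over a baseline period;
* per-month EOFs of the observed fields give environmental PC series;
* index coherence is the Spearman rank correlation between a species
  aggregation index and an environmental PC;
* lagged spatial correlation maps relate a spring aggregation index to
  each preceding month's field, cell by cell, flagging p < 0.05 cells
  (no multiplicity correction, matching conventional significance
  contours) — the winter pre-conditioning analysis.

The evaluation runs on the observation grid; the index is spatially
scalar and is never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .indices import EOFResult, IndexSeries, eof_decompose, compare_indices


@dataclass
class CorrelationMap:
    """Per-cell rank correlation of an annual index with a lag-month field."""

    rho: np.ndarray  # (lat, lon), NaN where no data
    p: np.ndarray
    significant: np.ndarray  # boolean, p < alpha among valid cells
    lag_month: int
    alpha: float = 0.05

    @property
    def significant_fraction(self) -> float:
        valid = np.isfinite(self.rho)
        return float(self.significant[valid].mean()) if valid.any() else np.nan


def compute_sla(ssh: xr.DataArray, baseline_years=None) -> xr.DataArray:
    """Sea level anomaly: SSH minus the per-cell monthly baseline mean.

    ``ssh`` is a monthly stack with a ``time`` coordinate; the baseline
    mean is computed per calendar month over ``baseline_years`` (default:
    all available years).
    """
    time = pd.DatetimeIndex(ssh["time"].values)
    if baseline_years is None:
        baseline_years = sorted(set(time.year))
    baseline_years = list(baseline_years)
    if not baseline_years:
        raise ValueError("empty SLA baseline period")
    missing = set(baseline_years) - set(time.year)
    if missing:
        raise ValueError(f"baseline years missing from record: {sorted(missing)}")
    sla = ssh.copy(deep=True)
    in_base = np.isin(time.year, baseline_years)
    for m in sorted(set(time.month)):
        sel = time.month == m
        base = ssh.values[sel & in_base].mean(axis=0)
        sla.values[sel] = ssh.values[sel] - base
    sla.name = "sla"
    return sla


def monthly_year_stack(field: xr.DataArray, month: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (year, lat, lon) stack of one calendar month."""
    time = pd.DatetimeIndex(field["time"].values)
    sel = time.month == month
    if not sel.any():
        raise ValueError(f"no data for month {month}")
    years = time.year[sel].to_numpy()
    order = np.argsort(years)
    return field.values[sel][order], years[order]


def env_eof_by_month(field: xr.DataArray, month: int) -> EOFResult:
    """EOF of one observed variable's year × cell matrix for one month."""
    stack, years = monthly_year_stack(field, month)
    if len(years) < 3:
        raise ValueError(f"month {month} has fewer than 3 years")
    return eof_decompose(stack, years)


def index_coherence(species_index: IndexSeries, env_pc: IndexSeries) -> tuple[float, float]:
    """Spearman coherence between an aggregation index and an env PC."""
    return compare_indices(species_index, env_pc)


def _percell_spearman(index: np.ndarray, cube: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-cell Spearman rho and two-sided t-approximation p.

    ``cube`` is (years, lat, lon) aligned with ``index``.
    """
    n, ny, nx = cube.shape
    flat = cube.reshape(n, -1)
    valid = np.isfinite(flat).all(axis=0)
    rho = np.full(flat.shape[1], np.nan)
    p = np.full(flat.shape[1], np.nan)
    if valid.any():
        ri = stats.rankdata(index)
        ri = (ri - ri.mean()) / ri.std()
        rf = stats.rankdata(flat[:, valid], axis=0).astype(float)
        rf -= rf.mean(axis=0)
        sd = rf.std(axis=0)
        sd[sd == 0] = np.nan
        rf /= sd
        r = ri @ rf / n
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1 - r**2))
        pv = 2 * stats.t.sf(np.abs(t), df=n - 2)
        pv[np.isclose(np.abs(r), 1.0)] = 0.0
        rho[valid] = r
        p[valid] = pv
    return rho.reshape(ny, nx), p.reshape(ny, nx)


def lagged_correlation_maps(
    species_index: IndexSeries,
    env: xr.DataArray,
    target_month: int = 5,
    from_month: int = 1,
    alpha: float = 0.05,
    min_overlap: int = 5,
) -> list[CorrelationMap]:
    """Lagged spatial correlation maps from ``from_month`` to the target.

    For each lag month, correlates the annual index with that month's
    field value in each grid cell across the overlapping years (Spearman,
    two-sided t-approximation p). Cells with fewer than ``min_overlap``
    overlapping years are NaN (no data, distinct from not-significant).
    """
    time = pd.DatetimeIndex(env["time"].values)
    maps = []
    for month in range(from_month, target_month + 1):
        sel = time.month == month
        years = time.year[sel].to_numpy()
        common, ia, ib = np.intersect1d(species_index.years, years, return_indices=True)
        if len(common) < min_overlap:
            ny, nx = env.shape[1:]
            maps.append(
                CorrelationMap(
                    rho=np.full((ny, nx), np.nan), p=np.full((ny, nx), np.nan),
                    significant=np.zeros((ny, nx), bool), lag_month=month, alpha=alpha,
                )
            )
            continue
        cube = env.values[np.flatnonzero(sel)[ib]]
        rho, p = _percell_spearman(species_index.values[ia], cube)
        sig = np.where(np.isfinite(p), p < alpha, False)
        maps.append(CorrelationMap(rho=rho, p=p, significant=sig, lag_month=month, alpha=alpha))
    return maps
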