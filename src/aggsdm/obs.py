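"""Observation processing: from raw 3-km transect bins to labeled records.

Raw sightings (one record per 3-km transect bin, with a behavior code)
are filtered to birds on the water or feeding, summed onto the analysis
grid per cell-day with survey effort providing true absences, filtered by
survey coverage and annual record counts, and labeled present/absent and
aggregating/non-aggregating. Aggregations are counts at or above the
species' empirical 90th percentile of positive counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

#: Behavior codes retained by the foraging filter.
RETAINED_BEHAVIORS = frozenset({"water", "feeding"})
VALID_BEHAVIORS = RETAINED_BEHAVIORS | {"flying"}

MIN_POSITIVE_FOR_CUTOFF = 10


class UnknownBehaviorError(ValueError):
    pass


class InsufficientPositivesError(ValueError):
    pass


@dataclass(frozen=True)
class AggregationThreshold:
    """Per-species aggregation cutoff.

    ``cutoff`` is the empirical 90th percentile (linear interpolation of
    order statistics at rank h = (n−1)·q) of positive counts; a count is
    labeled an aggregation when count ≥ cutoff.
    """

    species: str
    cutoff: float
    n_positive: int
    quantile: float = 0.9


def filter_behavior(raw: pd.DataFrame) -> pd.DataFrame:
    """Drop flying birds; keep records of birds on the water or feeding."""
    if "behavior" not in raw.columns:
        raise ValueError("sightings table lacks a 'behavior' column")
    unknown = set(raw["behavior"].unique()) - VALID_BEHAVIORS
    if unknown:
        raise UnknownBehaviorError(f"unknown behavior code(s): {sorted(unknown)}")
    return raw[raw["behavior"].isin(RETAINED_BEHAVIORS)].reset_index(drop=True)


def grid_sightings(
    filtered: pd.DataFrame, effort: pd.DataFrame, grid: GridSpec
) -> pd.DataFrame:
    """Sum sightings onto effort cell-days; absent species get count 0.

    Output has one row per (cell, date, species) over all surveyed
    cell-days: counts are summed within a cell-day, and surveyed cell-days
    where a species was not observed appear with count 0 (true absences,
    justified by the effort record). Cell membership follows the grid's
    half-open convention. Sightings outside the grid raise.
    """
    species = sorted(filtered["species"].unique()) if len(filtered) else []
    # repeat visits to a cell-day are separate transects: coverage adds
    # up to the whole cell
    eff = (
        effort.groupby(["date", "lat_idx", "lon_idx"], as_index=False)["coverage_fraction"]
        .sum()
    )
    eff["coverage_fraction"] = eff["coverage_fraction"].clip(upper=1.0)
    if len(filtered):
        iy, jx = grid.cell_of(filtered["lon"].to_numpy(), filtered["lat"].to_numpy())
        pos = filtered.assign(lat_idx=iy, lon_idx=jx)
        sums = (
            pos.groupby(["date", "lat_idx", "lon_idx", "species"], as_index=False)["count"]
            .sum()
        )
    else:
        sums = pd.DataFrame(columns=["date", "lat_idx", "lon_idx", "species", "count"])
    frames = []
    for sp in species or ["__none__"]:
        base = eff.copy()
        base["species"] = sp
        frames.append(base)
    full = pd.concat(frames, ignore_index=True) if frames else eff.assign(species=[])
    out = full.merge(sums, on=["date", "lat_idx", "lon_idx", "species"], how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    if not species:
        out = out.iloc[0:0]
    out["year"] = pd.DatetimeIndex(out["date"]).year if len(out) else []
    cols = ["date", "year", "lat_idx", "lon_idx", "species", "coverage_fraction", "count"]
    return out[cols].sort_values(["date", "lat_idx", "lon_idx", "species"]).reset_index(drop=True)


def apply_effort_filters(
    obs: pd.DataFrame,
    raw_records_per_year: pd.Series | dict,
    min_coverage: float = 0.05,
    min_year_records: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Apply the survey-quality filters and report what was dropped.

    Cells with coverage_fraction strictly below ``min_coverage`` are
    removed; years whose raw 3-km record count is strictly below
    ``min_year_records`` are removed entirely.
    """
    counts = pd.Series(dict(raw_records_per_year))
    bad_years = sorted(int(y) for y, c in counts.items() if c < min_year_records)
    low_cov = obs["coverage_fraction"] < min_coverage
    in_bad_year = obs["year"].isin(bad_years)
    report = {
        "dropped_low_coverage_rows": int((low_cov & ~in_bad_year).sum()),
        "dropped_years": bad_years,
        "dropped_year_rows": int(in_bad_year.sum()),
        "min_coverage": min_coverage,
        "min_year_records": min_year_records,
    }
    out = obs[~low_cov & ~in_bad_year].reset_index(drop=True)
    return out, report


def _interpolated_quantile(x: np.ndarray, q: float) -> float:
    """Empirical quantile by linear interpolation at rank h = (n−1)·q."""
    x = np.sort(np.asarray(x, dtype=float))
    h = (len(x) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(x) - 1)
    return float(x[lo] + (h - lo) * (x[hi] - x[lo]))


def compute_cutoff(
    positive_counts, species: str = "", quantile: float = 0.9
) -> AggregationThreshold:
    """Species aggregation cutoff: the 90th percentile of positive counts.

    Requires at least 10 positive counts; fitting an aggregation model on
    fewer labeled observations is not meaningful.
    """
    x = np.asarray(list(positive_counts), dtype=float)
    if len(x) < MIN_POSITIVE_FOR_CUTOFF:
        raise InsufficientPositivesError(
            f"only {len(x)} positive counts; need ≥ {MIN_POSITIVE_FOR_CUTOFF} "
            "to define an aggregation cutoff"
        )
    if np.any(x <= 0):
        raise ValueError("positive_counts must be strictly positive")
    return AggregationThreshold(
        species=species,
        cutoff=_interpolated_quantile(x, quantile),
        n_positive=len(x),
        quantile=quantile,
    )


def label_observations(
    obs: pd.DataFrame, thresholds: dict[str, AggregationThreshold]
) -> pd.DataFrame:
    """Attach presence (count > 0) and aggregation (count ≥ cutoff) labels."""
    missing = set(obs["species"].unique()) - set(thresholds)
    if missing:
        raise KeyError(f"no aggregation threshold for species: {sorted(missing)}")
    out = obs.copy()
    cut = out["species"].map({s: t.cutoff for s, t in thresholds.items()})
    out["presence"] = (out["count"] > 0).astype(int)
    out["aggregation"] = ((out["count"] >= cut) & (out["count"] > 0)).astype(int)
    return out


def threshold_sensitivity(
    positive_counts, quantiles=np.arange(0.85, 0.9501, 0.01), base_quantile: float = 0.9
) -> pd.DataFrame:
    """Cutoffs and label flips across a band of quantiles around 0.90.

    For each quantile, reports the cutoff, the number of labeled
    aggregations, and the fraction of labels that differ from the base
    (0.90) labeling — the robustness check behind the cutoff choice.
    """
    x = np.asarray(list(positive_counts), dtype=float)
    base = compute_cutoff(x, quantile=base_quantile)
    base_labels = x >= base.cutoff
    rows = []
    for q in np.atleast_1d(quantiles):
        cut = _interpolated_quantile(x, float(q))
        labels = x >= cut
        rows.append(
            {
                "quantile": float(q),
                "cutoff": cut,
                "n_labeled": int(labels.sum()),
                "flip_fraction": float((labels != base_labels).mean()),
            }
        )
    return pd.DataFrame(rows)


def aggregation_summary(labeled: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Per-species summary of labeled aggregations.

    Reports N aggregations, min/max/median/mean/SD of individuals within
    aggregations, and both candidate totals (sum over aggregations and
    sum over all positive counts).
    """
    rows = []
    for sp, t in thresholds.items():
        sub = labeled[labeled["species"] == sp]
        agg = sub.loc[sub["aggregation"] == 1, "count"]
        rows.append(
            {
                "species": sp,
                "cutoff": t.cutoff,
                "n_aggregations": int(len(agg)),
                "min": float(agg.min()) if len(agg) else np.nan,
                "max": float(agg.max()) if len(agg) else np.nan,
                "median": float(agg.median()) if len(agg) else np.nan,
                "mean": float(agg.mean()) if len(agg) else np.nan,
                "sd": float(agg.std()) if len(agg) else np.nan,
                "total_in_aggregations": int(agg.sum()),
                "total_positive": int(sub.loc[sub["presence"] == 1, "count"].sum()),
            }
        )
    return pd.DataFrame(rows)
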