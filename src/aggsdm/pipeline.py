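"""End-to-end pipeline orchestration.

Runs simulate → process → covariates → fit → predict → indices →
evaluate from a single config with a master seed, writing every
intermediate artifact plus a manifest (config hash, derived stage seeds,
artifact checksums). Re-running with an identical config reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import covariates as cov_mod
from . import evaluation as ev
from . import hurdle as hm
from . import indices as ix
from . import obs as obs_mod
from . import synthetic as syn
from .grid import GridSpec

log = logging.getLogger("aggsdm")

STAGES = ["simulate", "process", "fit", "predict", "indices", "evaluate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.record = {"stage": stage, "error": type(err).__name__, "message": str(err)}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Full configuration of a synthetic end-to-end run."""

    grid: GridSpec
    years: list
    days_per_year: int = 61
    visits_per_year: dict | int = 400
    species: list = field(default_factory=lambda: [syn.SpeciesSimConfig()])
    model: hm.ModelConfig = field(default_factory=hm.ModelConfig)
    forcing_sd: float = 1.0
    index_month: int = 5
    min_coverage: float = 0.05
    min_year_records: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("config must list at least one species")
        if not self.years:
            raise ValueError("config must list simulation years")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "species" not in d:
            raise ValueError("config missing 'species' block")
        d["grid"] = GridSpec(**d["grid"])
        d["species"] = [syn.SpeciesSimConfig(**s) for s in d["species"]]
        if "model" in d:
            d["model"] = hm.ModelConfig(**d["model"])
        d["years"] = [int(y) for y in d["years"]]
        if isinstance(d.get("visits_per_year"), dict):
            # serialized configs (YAML/JSON) carry string year keys
            d["visits_per_year"] = {int(k): int(v) for k, v in d["visits_per_year"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _visits_for_year(cfg: RunConfig, year: int) -> int:
    if isinstance(cfg.visits_per_year, dict):
        return int(cfg.visits_per_year[year])
    return int(cfg.visits_per_year)


def simulate_stage(cfg: RunConfig):
    seed = derive_seed(cfg.master_seed, "simulate")
    forcing = syn.ClimateForcing.random(cfg.years, seed=seed, sd=cfg.forcing_sd)
    env = syn.generate_environment(
        cfg.grid, cfg.years, cfg.days_per_year, forcing, seed=derive_seed(cfg.master_seed, "environment")
    )
    parts = []
    for y in cfg.years:
        parts.append(
            syn.generate_survey(
                cfg.grid, [y], _visits_for_year(cfg, y),
                seed=derive_seed(cfg.master_seed, f"survey:{y}"),
                days_per_year=cfg.days_per_year,
            )
        )
    effort = pd.concat(parts, ignore_index=True)
    sightings = {
        sp.name: syn.simulate_counts(
            env, effort, sp, forcing, seed=derive_seed(cfg.master_seed, f"counts:{sp.name}")
        )
        for sp in cfg.species
    }
    return env, effort, sightings, forcing


def process_stage(cfg: RunConfig, effort: pd.DataFrame, sightings: dict):
    """Behavior filter → gridding → effort filters → cutoffs → labels."""
    labeled_all, thresholds, reports = [], {}, {}
    for name, raw in sightings.items():
        filtered = obs_mod.filter_behavior(raw)
        gridded = obs_mod.grid_sightings(filtered, effort, cfg.grid)
        per_year = raw.groupby(pd.DatetimeIndex(raw["date"]).year).size()
        kept, report = obs_mod.apply_effort_filters(
            gridded, per_year, cfg.min_coverage, cfg.min_year_records
        )
        positives = kept.loc[kept["count"] > 0, "count"]
        thresholds[name] = obs_mod.compute_cutoff(positives, species=name)
        labeled_all.append(obs_mod.label_observations(kept, {name: thresholds[name]}))
        reports[name] = report
    labeled = pd.concat(labeled_all, ignore_index=True)
    return labeled, thresholds, reports


def fit_stage_all(cfg: RunConfig, labeled: pd.DataFrame, env: xr.Dataset):
    cov = cov_mod.derive_covariate_fields(env)
    ensembles, tables = {}, {}
    for sp in cfg.species:
        sub = labeled[labeled["species"] == sp.name]
        table, _rep = cov_mod.match_covariates(sub, cov)
        mcfg = dataclasses.replace(cfg.model, seed=derive_seed(cfg.master_seed, f"fit:{sp.name}"))
        ensembles[sp.name] = hm.fit_hurdle(table, mcfg)
        tables[sp.name] = table
    return cov, ensembles, tables


def predict_stage(cfg: RunConfig, cov: xr.Dataset, ensembles: dict, months=(4, 5, 6)):
    time = pd.DatetimeIndex(cov["time"].values)
    sel = np.isin(time.month, list(months))
    cov_sel = cov.isel(time=np.flatnonzero(sel))
    daily, monthly = {}, {}
    for name, ens in ensembles.items():
        d = hm.predict_hurdle(ens, cov_sel)
        daily[name] = d
        monthly[name] = hm.monthly_average(d, months=months)
    return daily, monthly


def indices_stage(cfg: RunConfig, monthly: dict):
    """EOF-PC1 and hotspot-area indices of the chosen month's fields."""
    out = {}
    for name, fields in monthly.items():
        months = pd.DatetimeIndex(fields["month"].values)
        sel = months.month == cfg.index_month
        stack = fields["pr_agg"].values[sel]
        years = months.year[sel].to_numpy()
        order = np.argsort(years)
        stack, years = stack[order], years[order]
        eof = ix.eof_decompose(stack, years)
        hot = ix.hotspot_area_index(stack, years)
        rho, p = ix.compare_indices(eof.pc(0), hot)
        out[name] = {"eof": eof, "hotspot": hot, "agreement_rho": rho, "agreement_p": p}
    return out


def evaluate_stage(cfg: RunConfig, env: xr.Dataset, species_indices: dict):
    """Independent evaluation against monthly means of the observed fields."""
    monthly_env = env[["sst", "ssh"]].resample(time="MS").mean()
    sla = ev.compute_sla(monthly_env["ssh"])
    results = {}
    sst_eof = ev.env_eof_by_month(monthly_env["sst"], cfg.index_month)
    sla_eof = ev.env_eof_by_month(sla, cfg.index_month)
    for name, idx in species_indices.items():
        rho_sst, p_sst = ev.index_coherence(idx["eof"].pc(0), sst_eof.pc(0))
        rho_sla, p_sla = ev.index_coherence(idx["eof"].pc(0), sla_eof.pc(0))
        maps = ev.lagged_correlation_maps(
            idx["eof"].pc(0), monthly_env["sst"], target_month=cfg.index_month,
            from_month=max(1, cfg.index_month - 4),
        )
        results[name] = {
            "rho_sst": rho_sst, "p_sst": p_sst,
            "rho_sla": rho_sla, "p_sla": p_sla,
            "lagged_maps": maps,
        }
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages, write artifacts, and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "master_seed": cfg.master_seed,
        "stages": [],
        "artifacts": {},
    }

    def record(stage, files):
        log.info("stage %s complete (%d artifacts)", stage, len(files))
        manifest["stages"].append(
            {"stage": stage, "seed": derive_seed(cfg.master_seed, stage), "artifacts": files}
        )

    try:
        env, effort, sightings, forcing = simulate_stage(cfg)
        env.to_netcdf(outdir / "environment.nc")
        effort.to_csv(outdir / "effort.csv", index=False)
        files = ["environment.nc", "effort.csv"]
        for name, tab in sightings.items():
            fn = f"sightings_{name}.csv"
            tab.to_csv(outdir / fn, index=False)
            files.append(fn)
        (outdir / "forcing.json").write_text(
            json.dumps({str(k): v for k, v in forcing.warm_index.items()}, indent=1)
        )
        files.append("forcing.json")
        record("simulate", files)

        labeled, thresholds, reports = process_stage(cfg, effort, sightings)
        labeled.to_csv(outdir / "labeled_obs.csv", index=False)
        (outdir / "exclusion_report.json").write_text(
            json.dumps(
                {
                    "filters": reports,
                    "cutoffs": {s: t.cutoff for s, t in thresholds.items()},
                },
                indent=1, default=str,
            )
        )
        record("process", ["labeled_obs.csv", "exclusion_report.json"])

        cov, ensembles, tables = fit_stage_all(cfg, labeled, env)
        files = []
        for name, e in ensembles.items():
            fn = f"metrics_{name}.csv"
            m = pd.concat(
                [e.presence.metrics.assign(stage="presence"),
                 e.aggregation.metrics.assign(stage="aggregation")]
            )
            m.to_csv(outdir / fn, index=False)
            vi = pd.DataFrame(
                {"presence": hm.variable_importance(e.presence),
                 "aggregation": hm.variable_importance(e.aggregation)}
            )
            vi.to_csv(outdir / f"importance_{name}.csv")
            files += [fn, f"importance_{name}.csv"]
        record("fit", files)

        daily, monthly = predict_stage(cfg, cov, ensembles)
        files = []
        for name in daily:
            daily[name].to_netcdf(outdir / f"pred_daily_{name}.nc")
            monthly[name].to_netcdf(outdir / f"pred_monthly_{name}.nc")
            files += [f"pred_daily_{name}.nc", f"pred_monthly_{name}.nc"]
        record("predict", files)

        sp_indices = indices_stage(cfg, monthly)
        rows = []
        for name, d in sp_indices.items():
            for series in (d["eof"].pc(0), d["hotspot"]):
                for y, v in zip(series.years, series.values):
                    rows.append({"species": name, "index": series.provenance,
                                 "year": int(y), "value": float(v)})
        pd.DataFrame(rows).to_csv(outdir / "indices.csv", index=False)
        record("indices", ["indices.csv"])

        eval_res = evaluate_stage(cfg, env, sp_indices)
        summary = {
            name: {
                "agreement_rho": sp_indices[name]["agreement_rho"],
                "agreement_p": sp_indices[name]["agreement_p"],
                "rho_sst": r["rho_sst"], "p_sst": r["p_sst"],
                "rho_sla": r["rho_sla"], "p_sla": r["p_sla"],
                "lag_significant_fraction": {
                    m.lag_month: (
                        None if not np.isfinite(m.significant_fraction) else m.significant_fraction
                    )
                    for m in r["lagged_maps"]
                },
            }
            for name, r in eval_res.items()
        }
        (outdir / "evaluation.json").write_text(json.dumps(summary, indent=1))
        record("evaluate", ["evaluation.json"])
    except StageError:
        raise
    except Exception as err:  # attribute failure to the stage reached so far
        stage = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "write"
        rec = StageError(stage, err)
        (outdir / "error.json").write_text(json.dumps(rec.record, indent=1))
        raise rec from err

    for st in manifest["stages"]:
        for fn in st["artifacts"]:
            manifest["artifacts"][fn] = _sha256(outdir / fn)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def make_fixture(small: bool = True, seed: int = 0) -> RunConfig:
    """Miniature run config exercising every code path in seconds.

    10×10 grid, six years of which one (the second) deliberately fails
    the 50-record annual filter, two species (a colony-bound resident and
    a migrant with opposite warm-mode response), and a small ensemble.
    Coverage fractions are uniform on (0, 1], so cells failing the 5%
    coverage filter occur by construction.
    """
    years = [2001, 2002, 2003, 2004, 2005, 2006]
    visits = {y: (30 if y == 2002 else 140) for y in years}
    if not small:
        visits = {y: (30 if y == 2002 else 400) for y in years}
    grid = GridSpec(-122.5, -121.5, 36.5, 37.5, 0.1)
    species = [
        syn.SpeciesSimConfig(name="resident", colony_decay_km=0.004, agg_forcing=1.2),
        syn.SpeciesSimConfig(name="migrant", agg_forcing=-1.2, patch_base_prob=0.15),
    ]
    model = hm.ModelConfig(
        n_members=3, max_trees=60, patience=5,
        learning_rate_presence=0.1, learning_rate_aggregation=0.05,
    )
    return RunConfig(
        grid=grid, years=years, days_per_year=61, visits_per_year=visits,
        species=species, model=model, master_seed=seed,
        min_year_records=50, index_month=5,
    )
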