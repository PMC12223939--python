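"""Two-stage hurdle model of species aggregation occurrence.

Stage one models presence/absence, stage two models aggregation given
presence, both as ensembles of boosted classification trees (bernoulli
loss, shallow interaction-depth-3 trees, stochastic row subsampling).
Each stage is an ensemble of ``n_members`` models, each fit on an
independent random 75/25 train/test split; held-out AUC and TSS are
recorded per member. The hurdle probability of aggregation is the
product of the two stage ensemble means:

    Pr(Agg) = Pr(presence) × Pr(Agg | presence)

computed cell by cell on daily covariate fields and then averaged into
calendar-month fields for the spring season. Leave-one-year-out (LOYO)
evaluation measures interannual transferability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .covariates import COVARIATE_NAMES

MIN_ROWS = 40


@dataclass
class ModelConfig:
    """Hyperparameters of the boosted-tree hurdle ensembles.

    Defaults follow standard practice for aggregation-scale seabird
    models: interaction depth 3, learning rate 0.01 (presence) and 0.005
    (aggregation), bag fraction 0.6, 50 members each trained on a fresh
    random 75/25 split. ``max_trees`` caps the stagewise iterations; each
    member stops early when its internal validation deviance has not
    improved for ``patience`` rounds.
    """

    tree_complexity: int = 3
    learning_rate_presence: float = 0.01
    learning_rate_aggregation: float = 0.005
    bag_fraction: float = 0.6
    n_members: int = 50
    train_fraction: float = 0.75
    max_trees: int = 2000
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.bag_fraction, self.train_fraction):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if min(self.n_members, self.max_trees, self.tree_complexity) < 1:
            raise ValueError("counts must be positive integers")

    def learning_rate(self, stage: str) -> float:
        return (
            self.learning_rate_presence
            if stage == "presence"
            else self.learning_rate_aggregation
        )


@dataclass
class StageEnsemble:
    """One hurdle stage: fitted members plus per-member held-out metrics."""

    stage: str
    members: list
    metrics: pd.DataFrame  # columns: member, auc, tss
    features: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble probability: mean of the members' probabilities."""
        p = np.zeros(len(X))
        for m in self.members:
            p += m.predict_proba(X)[:, 1]
        return p / len(self.members)


@dataclass
class HurdleEnsemble:
    presence: StageEnsemble
    aggregation: StageEnsemble
    config: ModelConfig = dc_field(default_factory=ModelConfig)

    @property
    def features(self) -> list[str]:
        return self.presence.features


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC; tied scores contribute one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def tss(scores, labels) -> float:
    """True skill statistic maximized over classification thresholds.

    TSS = sensitivity + specificity − 1 at the best threshold, scanned
    over every attainable operating point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.max(tpr - fpr))


def _fit_member(X, y, stage, cfg: ModelConfig, rs: int) -> GradientBoostingClassifier:
    model = GradientBoostingClassifier(
        loss="log_loss",
        learning_rate=cfg.learning_rate(stage),
        n_estimators=cfg.max_trees,
        max_depth=cfg.tree_complexity,
        subsample=cfg.bag_fraction,
        n_iter_no_change=cfg.patience,
        validation_fraction=0.1,
        random_state=rs,
    )
    model.fit(X, y)
    return model


def fit_stage(
    table: pd.DataFrame,
    stage: str,
    cfg: ModelConfig,
    features: list[str] | None = None,
    seed: int | None = None,
) -> StageEnsemble:
    """Fit one stage's ensemble of boosted-tree members.

    The presence stage uses every row (label = presence); the aggregation
    stage is conditional and uses presence-only rows (label =
    aggregation). Each member trains on an independent stratified
    ``train_fraction`` split and records AUC/TSS on its held-out quarter.
    """
    if stage not in ("presence", "aggregation"):
        raise ValueError(f"unknown stage '{stage}'")
    features = list(features or COVARIATE_NAMES)
    if stage == "aggregation":
        table = table[table["presence"] == 1]
    y = table[stage].to_numpy().astype(int)
    X = table[features].to_numpy(dtype=float)
    if len(y) < MIN_ROWS:
        raise ValueError(f"{len(y)} rows is too few to form meaningful splits")
    if y.min() == y.max():
        raise ValueError(f"single-class data for stage '{stage}'")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    members, rows = [], []
    for k in range(cfg.n_members):
        for _attempt in range(20):
            rs = int(rng.integers(0, 2**31 - 1))
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=cfg.train_fraction, stratify=y, random_state=rs
            )
            if ytr.min() != ytr.max() and yte.min() != yte.max():
                break
        else:
            raise ValueError("could not form a two-class train/test split")
        model = _fit_member(Xtr, ytr, stage, cfg, rs)
        p = model.predict_proba(Xte)[:, 1]
        members.append(model)
        rows.append({"member": k, "auc": auc(p, yte), "tss": tss(p, yte)})
    return StageEnsemble(stage, members, pd.DataFrame(rows), features)


def fit_hurdle(
    table: pd.DataFrame,
    cfg: ModelConfig,
    features: list[str] | None = None,
) -> HurdleEnsemble:
    """Fit both hurdle stages with stage-specific derived seeds."""
    pres = fit_stage(table, "presence", cfg, features, seed=cfg.seed)
    agg = fit_stage(table, "aggregation", cfg, features, seed=cfg.seed + 1)
    return HurdleEnsemble(pres, agg, cfg)


def predict_hurdle(ens: HurdleEnsemble, cov: xr.Dataset) -> xr.Dataset:
    """Daily hurdle prediction fields on the covariate grid.

    Per cell-day, each stage's probability is its ensemble mean and the
    aggregation probability is their product (averaging before
    multiplication). Cells with any missing covariate are NaN and counted
    in the ``n_masked`` attribute.
    """
    feats = ens.features
    shape = cov[feats[0]].shape  # (time, lat, lon)
    cols = []
    for name in feats:
        arr = cov[name].values
        if arr.ndim == 2:
            arr = np.broadcast_to(arr, shape)
        cols.append(arr.reshape(-1))
    X = np.column_stack(cols)
    ok = np.isfinite(X).all(axis=1)
    p1 = np.full(len(X), np.nan)
    p2 = np.full(len(X), np.nan)
    if ok.any():
        p1[ok] = ens.presence.predict(X[ok])
        p2[ok] = ens.aggregation.predict(X[ok])
    out = xr.Dataset(
        {
            "pr_presence": (("time", "lat", "lon"), p1.reshape(shape)),
            "pr_agg_given_presence": (("time", "lat", "lon"), p2.reshape(shape)),
            "pr_agg": (("time", "lat", "lon"), (p1 * p2).reshape(shape)),
        },
        coords={k: cov.coords[k] for k in ("time", "lat", "lon")},
        attrs={"n_masked": int((~ok).sum())},
    )
    return out


def monthly_average(daily: xr.Dataset, months=(4, 5, 6)) -> xr.Dataset:
    """Per-cell calendar-month means of the daily prediction fields.

    NaN days are excluded from the denominator; a year-month with no
    valid day is NaN with a warning.
    """
    time = pd.DatetimeIndex(daily["time"].values)
    keys = pd.Series(list(zip(time.year, time.month)))
    out_t, frames = [], []
    for (y, m), idx in keys.groupby(keys).groups.items():
        if m not in months:
            continue
        sub = daily.isel(time=np.asarray(idx))
        mean = sub.mean("time", skipna=True)
        if np.all(np.isnan(mean["pr_agg"].values)):
            warnings.warn(f"month {y}-{m:02d} has no valid days")
        out_t.append(pd.Timestamp(y, m, 1))
        frames.append(mean)
    if not frames:
        raise ValueError("daily fields span none of the requested months")
    stacked = xr.concat(frames, dim=pd.Index(out_t, name="month"))
    return stacked.sortby("month")


def loyo_evaluate(
    table: pd.DataFrame,
    cfg: ModelConfig,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-year-out evaluation of both stages.

    For each year, fits a single model per stage (same hyperparameters)
    on all other years and scores AUC/TSS on the held-out year. Years
    whose held-out rows are single-class for a stage are skipped with a
    warning and flagged in the output.
    """
    features = list(features or COVARIATE_NAMES)
    years = sorted(table["year"].unique())
    if len(years) < 3:
        raise ValueError("LOYO needs at least 3 distinct years")
    rows = []
    for i, yr in enumerate(years):
        train = table[table["year"] != yr]
        test = table[table["year"] == yr]
        for stage in ("presence", "aggregation"):
            tr = train[train["presence"] == 1] if stage == "aggregation" else train
            te = test[test["presence"] == 1] if stage == "aggregation" else test
            ytr, yte = tr[stage].to_numpy(), te[stage].to_numpy()
            if len(yte) == 0 or yte.min() == yte.max() or ytr.min() == ytr.max():
                warnings.warn(f"LOYO year {yr}, stage {stage}: single class; skipped")
                rows.append({"year": yr, "stage": stage, "scheme": "LOYO",
                             "auc": np.nan, "tss": np.nan, "skipped": True})
                continue
            model = _fit_member(
                tr[features].to_numpy(float), ytr.astype(int), stage, cfg,
                rs=cfg.seed + 1000 + i,
            )
            p = model.predict_proba(te[features].to_numpy(float))[:, 1]
            rows.append({"year": yr, "stage": stage, "scheme": "LOYO",
                         "auc": auc(p, yte), "tss": tss(p, yte), "skipped": False})
    return pd.DataFrame(rows)


def variable_importance(ens: StageEnsemble) -> pd.Series:
    """Mean relative influence per covariate, in percent (sums to 100).

    Per member, the summed loss reduction attributed to each covariate is
    normalized to 100; the ensemble value is the member mean.
    """
    if not ens.members:
        raise ValueError("ensemble has no fitted members")
    imp = np.zeros(len(ens.features))
    for m in ens.members:
        fi = m.feature_importances_
        tot = fi.sum()
        imp += 100 * fi / tot if tot > 0 else np.full_like(fi, 100 / len(fi))
    return pd.Series(imp / len(ens.members), index=ens.features)


def partial_dependence(
    ens: StageEnsemble, covariate: str, values, data: pd.DataFrame
) -> pd.DataFrame:
    """Mean ensemble response with one covariate clamped along a grid.

    For each grid value, the covariate column of ``data`` is clamped to
    that value and the ensemble-mean probability is averaged over rows.
    """
    if covariate not in ens.features:
        raise KeyError(f"covariate '{covariate}' not in model")
    X = data[ens.features].to_numpy(dtype=float).copy()
    j = ens.features.index(covariate)
    out = []
    for v in np.atleast_1d(values):
        X[:, j] = v
        out.append({"value": float(v), "response": float(ens.predict(X).mean())})
    return pd.DataFrame(out)
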