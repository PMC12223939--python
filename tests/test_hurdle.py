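"""Hurdle ensembles: metrics against brute-force oracles, stage fitting,
prediction bounds, LOYO, importances, and monthly averaging."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from aggsdm import (
    ModelConfig,
    auc,
    fit_hurdle,
    fit_stage,
    loyo_evaluate,
    monthly_average,
    partial_dependence,
    predict_hurdle,
    tss,
    variable_importance,
)

FAST = ModelConfig(
    n_members=5, max_trees=80, patience=5,
    learning_rate_presence=0.1, learning_rate_aggregation=0.1, seed=3,
)


def brute_auc(scores, labels):
    """Oracle: concordant-pair counting with half credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_tss(scores, labels):
    """Oracle: exhaustive scan over midpoint thresholds plus ±inf."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    uniq = np.sort(np.unique(s))
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = -np.inf
    for thr in cands:
        pred = s > thr
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestMetrics:
    scores = [0.1, 0.4, 0.35, 0.8]
    labels = [0, 0, 1, 1]

    def test_worked_auc_example(self):
        assert auc(self.scores, self.labels) == pytest.approx(0.75)
        assert brute_auc(self.scores, self.labels) == pytest.approx(0.75)

    def test_worked_tss_example(self):
        assert tss(self.scores, self.labels) == pytest.approx(0.5)
        assert brute_tss(self.scores, self.labels) == pytest.approx(0.5)

    def test_perfect_and_tied(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert tss([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            tss([0.1, 0.2], [0, 0])

    def test_oracle_equivalence_random_instances(self):
        """AUC matches pairwise counting and TSS matches the exhaustive
        threshold scan on 200 random instances with n ≤ 50."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert auc(s, y) == pytest.approx(brute_auc(s, y), abs=1e-12)
            assert tss(s, y) == pytest.approx(brute_tss(s, y), abs=1e-12)

    def test_null_tss_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [
            tss(rng.random(4000), rng.integers(0, 2, 4000)) for _ in range(5)
        ]
        assert np.mean(vals) < 0.07  # max-statistic bias only


def separable_table(n=2000, seed=0, n_noise=3):
    """Nearly separable binary outcome driven by one covariate."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1 + n_noise))
    y = (x[:, 0] + 0.15 * rng.normal(size=n) > 0).astype(int)
    cols = {"signal": x[:, 0]}
    cols.update({f"noise{i}": x[:, 1 + i] for i in range(n_noise)})
    df = pd.DataFrame(cols)
    df["presence"] = y
    df["aggregation"] = y
    return df


class TestFitStage:
    feats = ["signal", "noise0", "noise1", "noise2"]

    def test_informative_covariate_high_auc(self):
        ens = fit_stage(separable_table(), "presence", FAST, features=self.feats)
        assert ens.metrics["auc"].mean() >= 0.95
        assert len(ens.members) == FAST.n_members
        assert len(ens.metrics) == FAST.n_members

    def test_permuted_labels_null_auc(self):
        df = separable_table(n=2000, seed=1)
        rng = np.random.default_rng(5)
        df["presence"] = rng.permutation(df["presence"].to_numpy())
        ens = fit_stage(df, "presence", FAST, features=self.feats)
        assert ens.metrics["auc"].mean() == pytest.approx(0.5, abs=0.05)

    def test_single_class_and_tiny_data_rejected(self):
        df = separable_table(n=100)
        df["presence"] = 1
        with pytest.raises(ValueError, match="single-class"):
            fit_stage(df, "presence", FAST, features=self.feats)
        with pytest.raises(ValueError, match="too few"):
            fit_stage(separable_table(n=30), "presence", FAST, features=self.feats)

    def test_seed_determinism(self):
        df = separable_table(n=500, seed=2)
        e1 = fit_stage(df, "presence", FAST, features=self.feats)
        e2 = fit_stage(df, "presence", FAST, features=self.feats)
        pd.testing.assert_frame_equal(e1.metrics, e2.metrics)
        X = df[self.feats].to_numpy()
        np.testing.assert_array_equal(e1.predict(X), e2.predict(X))

    def test_aggregation_stage_uses_presence_rows_only(self):
        df = separable_table(n=600, seed=3)
        # aggregation labels defined (nontrivially) only among presences
        rng = np.random.default_rng(0)
        df.loc[df["presence"] == 1, "aggregation"] = rng.integers(
            0, 2, (df["presence"] == 1).sum()
        )
        ens = fit_stage(df, "aggregation", FAST, features=self.feats)
        n_pres = int((df["presence"] == 1).sum())
        # each member's train+test counts reflect the conditional subset
        assert ens.stage == "aggregation"
        assert len(ens.members) == FAST.n_members
        assert n_pres < len(df)


@pytest.fixture(scope="module")
def fitted(small_env, small_effort, small_grid):
    from aggsdm import (
        ClimateForcing,
        SpeciesSimConfig,
        compute_cutoff,
        filter_behavior,
        grid_sightings,
        label_observations,
        match_covariates,
        simulate_counts,
    )
    from aggsdm.covariates import derive_covariate_fields

    forcing = ClimateForcing({2001: 0.0, 2002: 2.0})
    raw = simulate_counts(small_env, small_effort, SpeciesSimConfig(), forcing, seed=21)
    gridded = grid_sightings(filter_behavior(raw), small_effort, small_grid)
    t = compute_cutoff(gridded.loc[gridded["count"] > 0, "count"], species="synthetic_species")
    labeled = label_observations(gridded, {"synthetic_species": t})
    cov = derive_covariate_fields(small_env)
    table, _ = match_covariates(labeled, cov)
    return cov, fit_hurdle(table, FAST)


class TestPredictionFields:

    def test_hurdle_product_and_bound(self, fitted):
        cov, ens = fitted
        pred = predict_hurdle(ens, cov)
        pa = pred["pr_agg"].values
        p1 = pred["pr_presence"].values
        p2 = pred["pr_agg_given_presence"].values
        np.testing.assert_allclose(pa, p1 * p2, atol=1e-12)
        assert np.all(pa <= np.minimum(p1, p2) + 1e-12)
        assert np.nanmin(pa) >= 0 and np.nanmax(pa) <= 1

    def test_masked_covariate_masks_output(self, fitted):
        cov, ens = fitted
        cov2 = cov.copy(deep=True)
        sst = cov2["sst"].values
        sst[0, 0, 0] = np.nan
        cov2["sst"] = (("time", "lat", "lon"), sst)
        pred = predict_hurdle(ens, cov2)
        assert np.isnan(pred["pr_agg"].values[0, 0, 0])
        assert pred.attrs["n_masked"] == 1

    def test_monthly_average_rules(self, small_grid):
        time = pd.date_range("2001-04-01", periods=30, freq="D")
        vals = np.zeros((30, 2, 2))
        vals[1::2] = 1.0  # alternating 0/1
        ds = xr.Dataset(
            {k: (("time", "lat", "lon"), vals.copy()) for k in
             ("pr_presence", "pr_agg_given_presence", "pr_agg")},
            coords={"time": time, "lat": [0.0, 0.1], "lon": [0.0, 0.1]},
        )
        out = monthly_average(ds, months=(4,))
        np.testing.assert_allclose(out["pr_agg"].values, 0.5)
        const = ds.copy(deep=True)
        for k in const.data_vars:
            const[k].values[:] = 0.3
        np.testing.assert_allclose(
            monthly_average(const, months=(4,))["pr_agg"].values, 0.3
        )


class TestLOYO:
    def test_fold_partition_and_metrics(self):
        rng = np.random.default_rng(11)
        n = 1500
        df = separable_table(n=n, seed=4)
        df["year"] = rng.integers(2001, 2006, n)
        df.loc[df["presence"] == 1, "aggregation"] = (
            df.loc[df["presence"] == 1, "signal"] + rng.normal(0, 1, (df["presence"] == 1).sum()) > 0
        ).astype(int)
        out = loyo_evaluate(df, FAST, features=["signal", "noise0", "noise1", "noise2"])
        assert sorted(out["year"].unique()) == [2001, 2002, 2003, 2004, 2005]
        assert set(out["stage"]) == {"presence", "aggregation"}
        ok = out[~out["skipped"]]
        assert (ok["auc"] > 0.5).mean() > 0.8  # signal transfers across years

    def test_fewer_than_three_years_rejected(self):
        df = separable_table(n=200)
        df["year"] = 2001
        with pytest.raises(ValueError):
            loyo_evaluate(df, FAST)


class TestImportanceAndDependence:
    def test_importance_sums_to_100(self):
        ens = fit_stage(separable_table(n=800, seed=5), "presence", FAST,
                        features=["signal", "noise0", "noise1", "noise2"])
        vi = variable_importance(ens)
        assert vi.sum() == pytest.approx(100, abs=1e-6)
        assert (vi >= 0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_generative_covariate_beats_noise(self, seed):
        cfg = ModelConfig(n_members=2, max_trees=40, patience=5,
                          learning_rate_presence=0.1, seed=seed)
        ens = fit_stage(separable_table(n=700, seed=seed), "presence", cfg,
                        features=["signal", "noise0", "noise1", "noise2"])
        vi = variable_importance(ens)
        assert vi["signal"] > max(vi["noise0"], vi["noise1"], vi["noise2"])

    def test_duplicated_covariate_shares_importance(self):
        df = separable_table(n=1200, seed=6)
        df["signal_dup"] = df["signal"]
        feats = ["signal", "signal_dup", "noise0"]
        ens_dup = fit_stage(df, "presence", FAST, features=feats)
        ens_one = fit_stage(df, "presence", FAST, features=["signal", "noise0"])
        vi_dup = variable_importance(ens_dup)
        vi_one = variable_importance(ens_one)
        combined = vi_dup["signal"] + vi_dup["signal_dup"]
        assert combined == pytest.approx(vi_one["signal"], abs=10.0)

    def test_monotone_effect_recovered(self):
        from scipy.stats import spearmanr

        # smooth logistic effect: the dependence curve rises over the
        # whole grid instead of saturating at the ends
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1500, 4))
        y = (rng.random(1500) < 1 / (1 + np.exp(-1.5 * x[:, 0]))).astype(int)
        df = pd.DataFrame(x, columns=["signal", "noise0", "noise1", "noise2"])
        df["presence"] = y
        ens = fit_stage(df, "presence", FAST, features=["signal", "noise0", "noise1", "noise2"])
        grid = np.linspace(-1.5, 1.5, 15)
        curve = partial_dependence(ens, "signal", grid, df)
        assert len(curve) == 15
        rho, _ = spearmanr(curve["value"], curve["response"])
        assert rho >= 0.9

    def test_unknown_covariate_rejected(self):
        ens = fit_stage(separable_table(n=500, seed=8), "presence", FAST,
                        features=["signal", "noise0", "noise1", "noise2"])
        with pytest.raises(KeyError):
            partial_dependence(ens, "not_a_covariate", [0.0], separable_table(n=50, seed=8))


class TestSyntheticRecovery:
    def test_default_species_auc_recovery(self, small_grid):
        """With the default generative species (~4000 obs), the presence
        stage reaches held-out AUC ≥ 0.8 and the aggregation stage ≥ 0.7."""
        from aggsdm import (
            ClimateForcing,
            SpeciesSimConfig,
            compute_cutoff,
            filter_behavior,
            generate_environment,
            generate_survey,
            grid_sightings,
            label_observations,
            match_covariates,
            simulate_counts,
        )
        from aggsdm.covariates import derive_covariate_fields

        years = list(range(2001, 2009))
        forcing = ClimateForcing.random(years, seed=31)
        env = generate_environment(small_grid, years, 40, forcing, seed=32)
        effort = generate_survey(small_grid, years, 520, seed=33, days_per_year=40)
        raw = simulate_counts(env, effort, SpeciesSimConfig(), forcing, seed=34)
        gridded = grid_sightings(filter_behavior(raw), effort, small_grid)
        t = compute_cutoff(gridded.loc[gridded["count"] > 0, "count"], species="synthetic_species")
        labeled = label_observations(gridded, {"synthetic_species": t})
        table, _ = match_covariates(labeled, derive_covariate_fields(env))
        assert len(table) > 3000
        ens = fit_hurdle(table, FAST)
        assert ens.presence.metrics["auc"].mean() >= 0.8
        assert ens.aggregation.metrics["auc"].mean() >= 0.7
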