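import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senescore import (
    AssociationError,
    CohortConfig,
    GridConfig,
    ModelSpec,
    age_acceleration_residuals,
    bh_fdr,
    build_analysis_sample,
    fit_linear_weighted,
    fit_logistic_weighted,
    generate_phenotypes,
    kfold_cv,
    run_model_grid,
    standardize_variables,
)

from oracles import bh_stepup_oracle


def tiny_table() -> pd.DataFrame:
    return pd.DataFrame({
        "vital_status": [1.0, 2.0, 3.0, 4.0],
        "score": [0.1, 0.2, 0.3, 0.4],
        "weight": [1.0, 1.0, 1.0, 1.0],
    }, index=[f"s{i}" for i in range(4)])


class TestAnalysisSample:
    def test_mortality_coding(self):
        spec = ModelSpec(outcome="mortality", family="logistic", focal="score",
                         covariates=(), batch_dummies=False)
        out = build_analysis_sample(tiny_table(), spec)
        assert out["mortality"].tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_presumed_alive_exclusion_drops_status_two(self):
        spec = ModelSpec(outcome="mortality", family="logistic", focal="score",
                         covariates=(), batch_dummies=False,
                         presumed_alive_exclusion=True)
        out = build_analysis_sample(tiny_table(), spec)
        assert len(out) == 3
        assert 2.0 not in set(out["vital_status"])

    def test_complete_case_per_model(self):
        t = tiny_table()
        t["extra"] = [1.0, np.nan, 2.0, 3.0]
        with_extra = ModelSpec(outcome="mortality", family="logistic",
                               focal="score", covariates=("extra",),
                               batch_dummies=False)
        without = ModelSpec(outcome="mortality", family="logistic",
                            focal="score", covariates=(), batch_dummies=False)
        assert len(build_analysis_sample(t, with_extra)) == 3
        assert len(build_analysis_sample(t, without)) == 4

    def test_unknown_status_code_rejected(self):
        t = tiny_table()
        t.loc["s0", "vital_status"] = 7.0
        spec = ModelSpec(outcome="mortality", family="logistic", focal="score",
                         covariates=(), batch_dummies=False)
        with pytest.raises(AssociationError, match="vital-status"):
            build_analysis_sample(t, spec)

    def test_outcome_among_predictors_rejected(self):
        with pytest.raises(AssociationError, match="predictors"):
            ModelSpec(outcome="pace", focal="pace", covariates=())


class TestStandardize:
    def test_continuous_zscore(self):
        t = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [2.0, 4.0, 6.0],
                          "weight": [1.0, 1.0, 1.0]})
        spec = ModelSpec(outcome="y", focal="x", covariates=(),
                         batch_dummies=False)
        y, X, w = standardize_variables(t, spec)
        np.testing.assert_allclose(X["x"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(y, [-1.0, 0.0, 1.0])

    def test_age_group_reference_gives_three_dummies(self, small_cohort):
        spec = ModelSpec(outcome="pace", covariates=("age_group",),
                         batch_dummies=False)
        sample = build_analysis_sample(small_cohort.phenotypes, spec)
        _, X, _ = standardize_variables(sample, spec)
        dummies = [c for c in X.columns if c.startswith("age_group[")]
        assert len(dummies) == 3
        assert not any("55-64" in c for c in dummies)

    def test_46_batches_give_45_dummies(self):
        rng = np.random.default_rng(0)
        n = 460
        t = pd.DataFrame({
            "y": rng.normal(size=n),
            "batch": [f"plate{(i % 46) + 1:02d}" for i in range(n)],
            "weight": np.ones(n),
        })
        spec = ModelSpec(outcome="y", covariates=(), batch_dummies=True)
        _, X, _ = standardize_variables(t, spec)
        assert sum(c.startswith("batch[") for c in X.columns) == 45

    def test_binary_predictors_stay_binary(self):
        t = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "female": [0, 1, 0, 1],
                          "weight": np.ones(4)})
        spec = ModelSpec(outcome="y", covariates=("female",), batch_dummies=False)
        _, X, _ = standardize_variables(t, spec)
        assert set(X["female"]) == {0.0, 1.0}

    def test_zero_variance_predictor_named(self):
        t = pd.DataFrame({"y": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0],
                          "weight": np.ones(3)})
        spec = ModelSpec(outcome="y", covariates=("flat",), batch_dummies=False)
        with pytest.raises(AssociationError, match="flat"):
            standardize_variables(t, spec)


class TestLinearFit:
    def test_perfect_fit(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"const": 1.0, "x": (x - x.mean()) / x.std(ddof=1)})
        res = fit_linear_weighted(X["x"], X, outcome="y", focal="x")
        assert res.focal_row()["estimate"] == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_null_focal_rarely_significant(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 500
            X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
            y = rng.normal(size=n)
            res = fit_linear_weighted(y, X, focal="x")
            row = res.focal_row()
            if abs(row["estimate"]) > 3 * row["se"]:
                hits += 1
        assert hits <= 5

    def test_frequency_weight_equivalence(self):
        rng = np.random.default_rng(2)
        n = 80
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        y = 0.5 * X["x"] + rng.normal(size=n)
        w = np.ones(n)
        w[: n // 2] = 2.0
        res_w = fit_linear_weighted(y, X, w, focal="x")
        X_exp = pd.concat([X, X.iloc[: n // 2]], ignore_index=True)
        y_exp = pd.concat([y, y.iloc[: n // 2]], ignore_index=True)
        res_e = fit_linear_weighted(y_exp.to_numpy(), X_exp, focal="x")
        assert res_w.focal_row()["estimate"] == pytest.approx(
            res_e.focal_row()["estimate"], abs=1e-10)

    def test_rank_deficiency_lists_columns(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = pd.DataFrame({"const": 1.0, "a": x, "b": 2 * x})
        with pytest.raises(AssociationError, match="rank deficient"):
            fit_linear_weighted(rng.normal(size=30), X)


class TestLogisticFit:
    def test_null_coverage(self):
        # Nominal 95% coverage; over 100 independent draws the binomial SD
        # is ~2.2, so 88 is a 3-sigma lower bound.
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(200 + seed)
            n = 400
            X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
            y = rng.binomial(1, 0.3, size=n)
            res = fit_logistic_weighted(y, X, focal="x")
            row = res.focal_row()
            if row["or_ci_low"] <= 1.0 <= row["or_ci_high"]:
                covered += 1
        assert covered >= 88

    def test_frequency_weight_equivalence(self):
        rng = np.random.default_rng(4)
        n = 120
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-(X["x"] - 1))))
        w = np.ones(n)
        w[: n // 2] = 2.0
        res_w = fit_logistic_weighted(y, X, w, focal="x")
        X_exp = pd.concat([X, X.iloc[: n // 2]], ignore_index=True)
        y_exp = np.concatenate([y, y[: n // 2]])
        res_e = fit_logistic_weighted(y_exp, X_exp, focal="x")
        assert res_w.focal_row()["estimate"] == pytest.approx(
            res_e.focal_row()["estimate"], abs=1e-8)

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(10), "x": np.arange(10.0)})
        with pytest.raises(AssociationError, match="single class"):
            fit_logistic_weighted(np.zeros(10), X)

    def test_complete_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        X = pd.DataFrame({"const": np.ones(40), "x": x})
        y = (x > 0).astype(float)
        with pytest.raises(AssociationError, match="separation|converge"):
            fit_logistic_weighted(y, X, focal="x")

    def test_zero_event_nuisance_dummy_dropped(self):
        rng = np.random.default_rng(5)
        n = 200
        d = np.zeros(n)
        d[:20] = 1.0
        y = rng.binomial(1, 0.3, size=n).astype(float)
        y[:20] = 0.0  # no events in the dummy cell
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n),
                          "batch[p2]": d})
        res = fit_logistic_weighted(y, X, focal="x")
        assert res.dropped_terms == ("batch[p2]",)
        assert "batch[p2]" not in res.terms.index


class TestAgeAcceleration:
    def test_identity_gives_zero_residuals(self):
        age = np.linspace(55, 90, 30)
        resid = age_acceleration_residuals(age, age)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_constant_offset_absorbed_by_intercept(self):
        age = np.linspace(55, 90, 30)
        resid = age_acceleration_residuals(age + 7.3, age)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_mean_exactly_zero(self):
        rng = np.random.default_rng(6)
        age = rng.uniform(56, 95, size=500)
        bio = age + rng.normal(scale=8.0, size=500)
        resid = age_acceleration_residuals(bio, age)
        assert abs(resid.mean()) < 1e-10

    def test_constant_age_rejected(self):
        with pytest.raises(AssociationError, match="constant"):
            age_acceleration_residuals(np.ones(5), np.ones(5))


class TestBHFDR:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_all_equal_collapse(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_small_vector_against_stepup(self):
        p = [0.01, 0.02, 0.03, 0.04]
        np.testing.assert_allclose(bh_fdr(p), bh_stepup_oracle(p), atol=1e-15)

    @pytest.mark.parametrize("trial", range(50))
    def test_random_vectors_match_oracle_and_statsmodels(self, trial):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3000 + trial)
        p = rng.uniform(size=int(rng.integers(1, 30)))
        got = bh_fdr(p)
        np.testing.assert_allclose(got, bh_stepup_oracle(p.tolist()), atol=1e-12)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(got, sm_adj, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_and_dominating(self, p):
        adj = bh_fdr(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(AssociationError):
            bh_fdr([0.5, 1.2])


class TestKFoldCV:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"const": np.ones(100), "x": rng.normal(size=100)})
        y = 2.0 + 3.0 * X["x"]
        cm = kfold_cv(y, X, k=5, seed=0)
        assert cm.mean_cv_r2 == pytest.approx(1.0, abs=1e-8)

    def test_pure_noise_cv_r2_near_zero(self):
        means = []
        for seed in range(50):
            rng = np.random.default_rng(400 + seed)
            X = pd.DataFrame({"const": np.ones(1000), "x": rng.normal(size=1000)})
            y = rng.normal(size=1000)
            means.append(kfold_cv(y, X, k=5, seed=seed).mean_cv_r2)
        assert np.mean(means) <= 0.02

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"const": np.ones(60), "x": rng.normal(size=60)})
        y = X["x"] + rng.normal(size=60)
        a = kfold_cv(y, X, k=4, seed=3)
        b = kfold_cv(y, X, k=4, seed=3)
        assert a.fold_r2 == b.fold_r2 and a.mean_cv_r2 == b.mean_cv_r2

    def test_cv_r2_below_full_r2_on_average(self):
        gaps = []
        for seed in range(50):
            rng = np.random.default_rng(500 + seed)
            n = 300
            X = pd.DataFrame({"const": np.ones(n), "x1": rng.normal(size=n),
                              "x2": rng.normal(size=n)})
            y = 0.4 * X["x1"] - 0.2 * X["x2"] + rng.normal(size=n)
            cm = kfold_cv(y, X, k=5, seed=seed)
            gaps.append(cm.full_r2 - cm.mean_cv_r2)
        assert np.mean(gaps) >= 0.0

    def test_stratified_logistic_folds(self):
        rng = np.random.default_rng(9)
        n = 300
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-X["x"])), size=n)
        cm = kfold_cv(y, X, family="logistic", k=5, seed=1)
        assert len(cm.fold_r2) == 5
        assert 0.0 < cm.rmse < 0.6


class TestModelGrid:
    @pytest.fixture(scope="class")
    @staticmethod
    def grid_out(small_cohort, small_scores):
        _, table = small_scores
        return run_model_grid(small_cohort.phenotypes, table.values,
                              GridConfig(run_cv=False))

    def test_grid_cardinality(self, grid_out):
        r = grid_out.results
        focal = r[(r["family"] == "outcome_on_score") & (r["term"] == r["score"])]
        # 5 scores x 6 outcomes, minus any recorded failures in that family
        fails = [f for f in grid_out.failures
                 if f["family"] == "outcome_on_score"]
        assert len(focal) + len(fails) == 30

    def test_score_models_present_for_all_scores(self, grid_out):
        r = grid_out.results
        fams = r[r["family"] == "score_on_factors"]
        assert set(fams["outcome"]) == {"CSP", "SIP", "SRP", "Summary", "SenMayo"}

    def test_fdr_not_below_raw(self, grid_out):
        r = grid_out.results.dropna(subset=["p_fdr"])
        assert (r["p_fdr"] >= r["p"] - 1e-12).all()

    def test_mortality_models_logistic_with_or(self, grid_out):
        r = grid_out.results
        mort = r[(r["outcome"] == "mortality") & (r["term"] == r["score"])]
        assert (mort["estimate_type"] == "log_or").all()
        assert (mort["odds_ratio"] > 0).all()

    def test_pace_adjusted_family_excludes_pace_outcome(self, grid_out):
        r = grid_out.results
        pace_adj = r[r["family"] == "outcome_on_score_pace"]
        assert "pace" not in set(pace_adj["outcome"])
        assert "pace" in set(pace_adj["term"])

    def test_pace_adjustment_attenuates_mediated_effect(self):
        # The pace outcome is driven by the same latent factor as the score,
        # so conditioning on pace must shrink the score's coefficient for a
        # downstream outcome on average.
        from senescore import generate_cohort, normalize, score_all

        diffs = []
        for seed in range(8):
            cfg = CohortConfig(n_samples=900, n_genes=250, seed=700 + seed,
                               covariate_effects={},
                               outcome_effects={"pace": 0.45, "clock_aa": 0.45})
            cohort = generate_cohort(cfg)
            table = score_all(normalize(cohort.counts), cohort.gene_sets)
            out = run_model_grid(
                cohort.phenotypes, table.values,
                GridConfig(scores=("Summary",),
                           outcome_families={"clock_aa": "linear"}))
            r = out.results
            base = r[(r["family"] == "outcome_on_score")
                     & (r["term"] == "Summary")]["estimate"].iloc[0]
            adj = r[(r["family"] == "outcome_on_score_pace")
                    & (r["term"] == "Summary")]["estimate"].iloc[0]
            diffs.append(abs(base) - abs(adj))
        assert np.mean(diffs) > 0.0
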