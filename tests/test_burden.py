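import numpy as np
import pandas as pd
import pytest

from mc1rburden import (
    ModelSpec,
    adjust_bh,
    age_equivalence,
    build_design,
    effect_summary,
    fit_negbin,
    impute_missing,
    pool_rubin,
    run_burden_analysis,
    yale_config,
    generate_cohort,
)
from mc1rburden.burden import NBFit, DegenerateDesignError
from mc1rburden.spectrum import CLASSES6, CONTEXTS96


def _cohort_with_counts(n=120, seed=0, missing_in=None, rate=0.15):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "r_present": rng.random(n) < 0.45,
            "r_count": rng.integers(0, 2, n),
            "age": np.round(rng.normal(58, 14, n), 1),
            "sex": rng.choice(["M", "F"], n),
            "sample_type": rng.choice(["primary", "metastasis"], n),
        }
    )
    for i, cls in enumerate(CLASSES6):
        df[cls] = rng.poisson(30 + 10 * i, n)
    if missing_in:
        for col in missing_in:
            mask = rng.random(n) < rate
            df[col] = df[col].astype(object)
            df.loc[mask, col] = np.nan
    return df


class TestImpute:
    def test_complete_data_gives_identical_copies(self):
        cohort = _cohort_with_counts()
        out = impute_missing(cohort, m=3, seed=1)
        assert len(out) == 3
        for d in out:
            pd.testing.assert_frame_equal(
                d.reset_index(drop=True), cohort.reset_index(drop=True),
                check_dtype=False,
            )

    def test_imputed_copies_are_complete_and_vary(self):
        cohort = _cohort_with_counts(missing_in=["age", "sex"])
        out = impute_missing(cohort, m=4, seed=2)
        for d in out:
            assert not d["age"].isna().any() and not d["sex"].isna().any()
        ages = np.array([d["age"].to_numpy(dtype=float) for d in out])
        assert np.std(ages, axis=0).max() > 0  # imputations differ across copies

    def test_observed_cells_untouched(self):
        cohort = _cohort_with_counts(missing_in=["age"])
        obs = ~cohort["age"].isna()
        out = impute_missing(cohort, m=2, seed=3)
        for d in out:
            assert np.allclose(
                d.loc[obs, "age"].astype(float), cohort.loc[obs, "age"].astype(float)
            )

    def test_rare_level_set_to_missing_and_imputed(self):
        cohort = _cohort_with_counts(n=80, seed=5)
        cohort["centre"] = ["A"] * 77 + ["ZZ"] * 3  # level with <5 samples
        out = impute_missing(cohort, m=2, seed=1, covariates=["age", "centre"])
        for d in out:
            assert "ZZ" not in set(d["centre"])
            assert not d["centre"].isna().any()

    def test_fully_missing_column_errors(self):
        cohort = _cohort_with_counts()
        cohort["age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            impute_missing(cohort, m=2, seed=1)

    def test_pmm_beats_marginal_draw_oracle(self):
        """Conditional (PMM) imputation of MCAR ages must beat imputing
        from the unconditional age distribution, averaged over replicates.

        Age is made strongly predictable from a correlate so the chained
        model has signal to exploit."""
        pmm_err, marginal_err = [], []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 250
            true_age = rng.normal(58, 14, n)
            cohort = pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(n)],
                    "r_present": rng.random(n) < 0.5,
                    # strongly age-correlated auxiliary covariate
                    "breslow": np.exp(0.03 * (true_age - 58) + rng.normal(0, 0.1, n)),
                    "age": true_age,
                }
            )
            for cls in CLASSES6:
                cohort[cls] = rng.poisson(30, n)
            mask = rng.random(n) < 0.12
            cohort.loc[mask, "age"] = np.nan
            d = impute_missing(cohort, m=1, seed=rep, covariates=["age", "breslow"])[0]
            pmm_err.append(np.abs(d.loc[mask, "age"] - true_age[mask]).mean())
            marg = rng.choice(true_age[~mask], size=int(mask.sum()))
            marginal_err.append(np.abs(marg - true_age[mask]).mean())
        assert np.mean(pmm_err) < np.mean(marginal_err)


class TestFitNegbin:
    def test_intercept_only_recovers_sample_mean(self, rng):
        y = rng.poisson(20, 400)
        X = pd.DataFrame({"const": np.ones(400)})
        fit = fit_negbin(y, X)
        assert np.exp(fit.beta("const")) == pytest.approx(y.mean(), rel=1e-4)

    def test_poisson_limit_matches_poisson_oracle(self, rng):
        """On Poisson data (theta -> inf) the NB fit matches a Poisson
        regression fit to 1e-3."""
        import statsmodels.api as sm

        n = 2000
        x = rng.random(n) < 0.5
        mu = np.exp(3.0 + 0.4 * x)
        y = rng.poisson(mu)
        X = pd.DataFrame({"const": np.ones(n), "x": x.astype(float)})
        fit = fit_negbin(y, X)
        oracle = sm.Poisson(y, X.to_numpy()).fit(disp=0)
        assert fit.beta("const") == pytest.approx(oracle.params[0], abs=1e-3)
        assert fit.beta("x") == pytest.approx(oracle.params[1], abs=1e-3)
        assert fit.theta > 50  # dispersion pushed toward the Poisson limit

    def test_theta_recovered_on_nb_data(self, rng):
        n, theta, mu = 4000, 2.0, 50.0
        lam = rng.gamma(theta, mu / theta, n)
        y = rng.poisson(lam)
        fit = fit_negbin(y, pd.DataFrame({"const": np.ones(n)}))
        assert fit.theta == pytest.approx(theta, rel=0.2)

    def test_rejects_bad_counts(self):
        X = pd.DataFrame({"const": np.ones(3)})
        with pytest.raises(ValueError):
            fit_negbin(np.array([1.5, 2.0, 3.0]), X)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame(
            {"sample_id": ["a", "b"], "r_present": [True, True], "age": [50.0, 60.0]}
        )
        spec = ModelSpec(covariates=("age",))
        X = build_design(df, spec)
        assert "r_present" not in X.columns  # constant column dropped
        df2 = df.assign(age2=df["age"])
        with pytest.raises(DegenerateDesignError):
            spec2 = ModelSpec(covariates=("age", "breslow"))
            build_design(df2.assign(breslow=np.exp(df2["age"])), spec2)


class TestPooling:
    @staticmethod
    def _fit(beta, var, n=100):
        return NBFit(
            coefficients={"x": (beta, float(np.sqrt(var)))},
            theta=1.0, loglik=-1.0, n=n,
        )

    def test_hand_computed_rubin_formulas(self):
        fits = [self._fit(b, 0.01) for b in (0.30, 0.35, 0.40)]
        pooled = pool_rubin(fits)
        assert pooled.loc["x", "beta"] == pytest.approx(0.35)
        # B = var([0.30, 0.35, 0.40], ddof=1) = 0.0025
        total_var = 0.01 + (1 + 1 / 3) * 0.0025
        assert pooled.loc["x", "se"] ** 2 == pytest.approx(total_var, rel=1e-9)

    def test_single_fit_pools_to_itself(self):
        pooled = pool_rubin([self._fit(0.3, 0.01)])
        assert pooled.loc["x", "beta"] == pytest.approx(0.3)
        assert pooled.loc["x", "se"] == pytest.approx(0.1)
        assert pooled.loc["x", "between_se"] == 0.0

    def test_identical_fits_have_within_se_only(self):
        pooled = pool_rubin([self._fit(0.3, 0.01) for _ in range(5)])
        assert pooled.loc["x", "se"] == pytest.approx(0.1)

    def test_zero_fits_error(self):
        with pytest.raises(ValueError):
            pool_rubin([])


class TestBHAndEffects:
    def test_bh_all_equal(self):
        assert np.allclose(adjust_bh([0.03] * 6), 0.03)

    def test_bh_step_up_enumerated(self):
        adj = adjust_bh([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        assert np.allclose(adj, 0.06)

    def test_bh_smallest_scaled_by_m(self):
        adj = adjust_bh([0.001, 1.0, 0.9, 0.8, 0.7, 0.6])
        assert adj[np.argmin([0.001, 1.0, 0.9, 0.8, 0.7, 0.6])] == pytest.approx(0.006)

    def test_bh_monotone_and_capped(self, rng):
        p = rng.random(6)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p)

    def test_effect_summary_values(self):
        assert effect_summary(0.0, 0.1, 100)["percent_change"] == 0.0
        assert effect_summary(np.log(1.42), 0.1, 1e6)["percent_change"] == pytest.approx(42.0)
        assert effect_summary(np.log(1.017), 0.01, 1e6)["percent_change"] == pytest.approx(1.7)
        s = effect_summary(0.3, 0.1, 50)
        assert s["ci_low"] < s["percent_change"] < s["ci_high"]

    def test_age_equivalence(self):
        assert age_equivalence(np.log(1.42), np.log(1.017)) == pytest.approx(20.8, abs=0.05)
        assert age_equivalence(0.0, 0.02) == 0.0
        assert age_equivalence(0.02, 0.02) == 1.0
        with pytest.raises(ZeroDivisionError):
            age_equivalence(0.3, 0.0)


class TestRunBurdenAnalysis:
    def test_six_class_mode_has_bh(self, small_yale_cohort):
        cohort, _ = small_yale_cohort
        spec = ModelSpec(covariates=("age", "sex", "sample_type"))
        an = run_burden_analysis(cohort, spec, m=1, seed=0)
        assert set(an.results) == set(CLASSES6)
        for r in an.results.values():
            assert r.p_adjusted is not None and r.p_adjusted >= r.p_raw - 1e-12
            assert r.age_equiv_years is not None

    def test_total_mode_single_result_no_bh(self, small_yale_cohort):
        cohort, _ = small_yale_cohort
        spec = ModelSpec(response="total", covariates=("age", "sex", "sample_type"))
        an = run_burden_analysis(cohort, spec, m=1, seed=0)
        assert list(an.results) == ["total"]
        assert an.results["total"].p_adjusted is None

    def test_presence_and_count_agree_without_two_R_samples(self):
        cohort = _cohort_with_counts(n=150, seed=11)  # r_count in {0, 1}
        cohort["r_present"] = cohort["r_count"] >= 1
        kw = dict(m=1, seed=0)
        pres = run_burden_analysis(
            cohort, ModelSpec(response="C>A", covariates=("age",)), **kw
        )
        cnt = run_burden_analysis(
            cohort,
            ModelSpec(response="C>A", r_predictor="count", covariates=("age",)),
            **kw,
        )
        b1 = pres.results["C>A"].pooled.loc["r_present", "beta"]
        b2 = cnt.results["C>A"].pooled.loc["r_count_1", "beta"]
        assert b1 == pytest.approx(b2, abs=1e-5)

    def test_pooling_complete_data_equals_single_fit(self, small_yale_cohort):
        cohort, _ = small_yale_cohort
        spec = ModelSpec(response="C>T", covariates=("age", "sex", "sample_type"))
        a1 = run_burden_analysis(cohort, spec, m=1, seed=0)
        a5 = run_burden_analysis(cohort, spec, m=5, seed=1)
        b1 = a1.results["C>T"].pooled.loc["r_present", "beta"]
        b5 = a5.results["C>T"].pooled.loc["r_present", "beta"]
        assert b1 == pytest.approx(b5, abs=1e-8)

    def test_table_shape(self, small_yale_cohort):
        cohort, _ = small_yale_cohort
        spec = ModelSpec(covariates=("age", "sex", "sample_type"))
        table = run_burden_analysis(cohort, spec, m=1, seed=0).table()
        assert list(table["class"]) == list(CLASSES6)
        assert {"percent_change", "ci_low", "ci_high", "p_raw", "p_adjusted"} <= set(table)
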