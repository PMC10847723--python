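import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import expit, logit

import seasonscan as ss
from seasonscan.envglm import (
    DEFAULT_WINDOWS,
    SUMMARY_IDS,
    best_model,
    build_env_covariates,
    build_model_grid,
    design_matrices,
    fit_binomial_many,
    fit_snp_models,
    likelihood_ratio_test,
    permute_design,
    relative_rate,
    run_glm_battery,
)
from seasonscan.synth import gen_weather


class TestCovariateGrid:
    def test_grid_enumerates_110_covariates(self, small_study, small_cov):
        assert len(DEFAULT_WINDOWS) == 11 and len(SUMMARY_IDS) == 10
        assert small_cov.shape[1] == 110

    def test_model_grid_enumerates_112(self, small_cov):
        grid = build_model_grid(small_cov.columns)
        assert len(grid) == 112
        kinds = pd.Series([m.kind for m in grid]).value_counts()
        assert kinds["null"] == 1 and kinds["time"] == 1
        assert kinds["environmental"] == 110

    def test_constant_tmax_gives_zero_prop_hot(self):
        w = gen_weather(400, seed=0, seasonal_amplitude=0.0, noise_sd=0.0, mean_temp=26.0)
        assert w["tmax"].iloc[0] == pytest.approx(30.0)
        meta = pd.DataFrame(
            {
                "sample": ["a"],
                "locality": ["x"],
                "date": [w["date"].iloc[-1]],
                "year": [2016],
            }
        )
        cov = build_env_covariates(w, meta)
        prop_cols = [c for c in cov.columns if c.startswith("temp_propmax")]
        assert (cov[prop_cols].to_numpy() == 0).all()

    def test_prop_hot_direct_count(self):
        # daily maxima {33, 31, 35, 30} in a 0-3d window -> prop 0.5
        dates = pd.date_range("2020-06-01", periods=10)
        w = pd.DataFrame(
            {
                "date": dates,
                "tmax": [20.0] * 6 + [30.0, 35.0, 31.0, 33.0],
                "tmin": [10.0] * 10,
                "precip": 0.0,
                "rh": 50.0,
            }
        )
        meta = pd.DataFrame(
            {
                "sample": ["a"],
                "locality": ["x"],
                "date": [dates[-1]],
                "year": [2020],
            }
        )
        cov = build_env_covariates(w, meta, windows=[(0, 3)])
        assert cov.loc["a", "temp_propmax_0-3d"] == pytest.approx(0.5)

    def test_insufficient_coverage_names_sample(self):
        w = gen_weather(130, seed=0)
        meta = pd.DataFrame(
            {
                "sample": ["late_sample"],
                "locality": ["x"],
                "date": [w["date"].iloc[10]],  # only 10 days of history
                "year": [2016],
            }
        )
        with pytest.raises(ValueError, match="late_sample"):
            build_env_covariates(w, meta)


def _irls_oracle(y, w, X, n_iter=200):
    """Brute-force scalar IRLS for one SNP (independent of the library path)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        W = np.diag(w * mu * (1 - mu))
        z = eta + (y - mu) / (mu * (1 - mu))
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
    mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
    ll = np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return beta, ll


class TestBinomialFits:
    def test_matches_scalar_irls_oracle(self):
        rng = np.random.default_rng(0)
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.uniform(0.2, 0.8, n)
        w = rng.uniform(20, 60, n)
        fit = fit_binomial_many(y[None, :], w[None, :], X)
        beta_o, ll_o = _irls_oracle(y, w, X)
        np.testing.assert_allclose(fit["beta"][0], beta_o, atol=1e-6)
        assert fit["loglik"][0] == pytest.approx(ll_o, abs=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.uniform(0.1, 0.9, n)
        w = rng.uniform(10, 50, n)
        fit = fit_binomial_many(y[None, :], w[None, :], X)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        np.testing.assert_allclose(fit["beta"][0], ref.params, atol=1e-6)

    def test_missing_cells_ignored(self):
        rng = np.random.default_rng(2)
        n = 8
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.uniform(0.2, 0.8, n)
        w = np.full(n, 30.0)
        y_miss = y.copy()
        y_miss[3] = np.nan
        fit_miss = fit_binomial_many(y_miss[None, :], w[None, :], X)
        keep = np.arange(n) != 3
        fit_sub = fit_binomial_many(y[None, keep], w[None, keep], X[keep])
        np.testing.assert_allclose(fit_miss["beta"][0], fit_sub["beta"][0], atol=1e-8)

    def test_nesting_never_reduces_loglik(self, small_study, small_cov):
        fits = fit_snp_models(
            small_study.afm, small_cov.iloc[:, :5], meta=small_study.meta
        )
        wide = fits.pivot(index="snp", columns="model", values="loglik")
        conv = fits.pivot(index="snp", columns="model", values="converged")
        ok = conv.all(axis=1)
        assert (wide.loc[ok, "time"] >= wide.loc[ok, "null"] - 1e-6).all()
        env_cols = [c for c in wide.columns if c not in ("null", "time")]
        for c in env_cols:
            assert (wide.loc[ok, c] >= wide.loc[ok, "time"] - 1e-6).all()

    def test_constant_af_time_lrt_null(self):
        n = 12
        meta = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(n)],
                "locality": "x",
                "date": pd.date_range("2016-07-01", periods=n),
                "year": np.repeat([2016, 2017, 2018], 4),
            }
        )
        af = np.full((1, n), 0.4)
        snps = pd.DataFrame({"chrom": ["2L"], "pos": [100], "ref": "A", "alt": "T"})
        afm = ss.AlleleFrequencyMatrix(
            snps=snps,
            samples=meta["sample"].tolist(),
            af=af,
            depth=np.full((1, n), 60.0),
            n_chrs=np.full(n, 80.0),
        )
        cov = pd.DataFrame({"c1": np.arange(n, dtype=float)}, index=meta["sample"])
        fits = fit_snp_models(afm, cov, meta=meta)
        p_time = fits.loc[fits["model"] == "time", "lrt_p"].iloc[0]
        assert p_time > 0.99


class TestLrt:
    def test_identical_fits_give_p_one(self):
        p, stat, flagged = likelihood_ratio_test(-10.0, -10.0, 1)
        assert stat == 0 and p == 1.0

    def test_chi2_quantile(self):
        p, _, _ = likelihood_ratio_test(-8.0795, -10.0, 1)  # stat = 3.841
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_clamped_and_flagged(self):
        p, stat, flagged = likelihood_ratio_test(-11.0, -10.0, 1)
        assert stat == 0 and p == 1.0 and flagged


class TestBestModel:
    def test_only_converged_models_eligible(self):
        out = best_model(
            [5.0, 3.0], ["null", "time"], [1, 3], converged=[True, False]
        )
        assert out == "null"

    def test_tie_prefers_fewer_parameters(self):
        out = best_model([10.0, 10.0, 10.0], ["envB", "time", "envA"], [4, 3, 4])
        assert out == "time"

    def test_tie_then_lexicographic(self):
        out = best_model([10.0, 10.0], ["envB", "envA"], [4, 4])
        assert out == "envA"

    def test_matches_brute_force_argmin_on_toy_table(self):
        aic = [101.2, 99.9, 100.4, 98.7, 99.9]
        ids = ["null", "time", "env1", "env2", "env3"]
        k = [1, 3, 4, 4, 4]
        assert best_model(aic, ids, k) == ids[int(np.argmin(aic))]

    def test_no_converged_returns_none(self):
        assert best_model([1.0], ["null"], [1], converged=[False]) is None


class TestPermutations:
    def test_same_seed_reproduces(self, small_study):
        p1 = permute_design(small_study.meta, n_perm=5, seed=3)
        p2 = permute_design(small_study.meta, n_perm=5, seed=3)
        np.testing.assert_array_equal(p1, p2)

    def test_identity_permutation_equals_real(self, small_study, small_cov):
        cov5 = small_cov.iloc[:, :3]
        fits = fit_snp_models(small_study.afm, cov5, meta=small_study.meta)
        # applying the identity ordering to the covariates reproduces the fits
        ident = np.arange(small_study.afm.n_samples)
        cov_perm = cov5.iloc[ident]
        cov_perm.index = cov5.index
        fits2 = fit_snp_models(small_study.afm, cov_perm, meta=small_study.meta)
        pd.testing.assert_frame_equal(fits, fits2)

    def test_null_generator_lrt_uniform(self, null_study):
        # with all planted effects zero the covariate LRT p-values are
        # uniform, both for the real covariate ordering and under permutation
        cov = build_env_covariates(null_study.weather, null_study.meta)
        focal = null_study.planted_variable
        bat = run_glm_battery(
            null_study.afm,
            null_study.meta,
            cov[[focal]],
            n_perm=5,
            seed=5,
            track_perm_p_for=[focal],
        )
        real_p = bat.env_lrt_p[focal].to_numpy()
        real_p = real_p[np.isfinite(real_p)]
        assert sps.kstest(real_p, "uniform").pvalue > 0.01
        perm_p = bat.perm_env_lrt_p[focal].ravel()
        perm_p = perm_p[np.isfinite(perm_p)]
        assert abs(perm_p.mean() - 0.5) < 0.05


class TestRelativeRate:
    def test_equal_counts_give_zero(self):
        real = np.array(["m1"] * 40 + ["m2"] * 60, dtype=object)
        perm = np.stack([real.copy() for _ in range(10)])
        rr = relative_rate(real, perm, ["m1", "m2"])
        assert (rr["mean_rr"] == 0).all()
        assert not rr["significant"].any()

    def test_log2_ratio_exact(self):
        real = np.array(["m1"] * 40 + ["x"] * 60, dtype=object)
        one_perm = np.array(["m1"] * 10 + ["x"] * 90, dtype=object)
        perm = np.stack([one_perm for _ in range(8)])
        rr = relative_rate(real, perm, ["m1"])
        assert rr.loc[0, "mean_rr"] == pytest.approx(2.0)  # log2(40/10)
        assert rr.loc[0, "sigma_rr"] == 0.0
        assert rr.loc[0, "significant"]

    def test_zero_perm_count_pseudocounted_and_flagged(self):
        real = np.array(["m1"] * 4, dtype=object)
        perm = np.stack([np.array(["x"] * 4, dtype=object)] * 5)
        rr = relative_rate(real, perm, ["m1"])
        assert rr.loc[0, "pseudocount_flagged"]
        assert rr.loc[0, "mean_rr"] == pytest.approx(np.log2(4.5 / 0.5))

    def test_planted_model_enriched_only_inside_block(self, small_study, small_cov):
        bat = run_glm_battery(
            small_study.afm,
            small_study.meta,
            small_cov,
            n_perm=8,
            seed=6,
        )
        regions = np.where(
            small_study.truth["in_inversion_block"].to_numpy(), "inv", "out"
        )
        rr = relative_rate(bat.real_best, bat.perm_best, bat.model_ids, regions)
        focal = small_study.planted_variable
        inside = rr[(rr.region == "inv") & (rr.model == focal)].iloc[0]
        outside = rr[(rr.region == "out") & (rr.model == focal)].iloc[0]
        assert inside["significant"] and inside["mean_rr"] > 0
        assert not (outside["significant"] and outside["mean_rr"] > 0)
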