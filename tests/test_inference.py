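"""Poisson offset regression, GEE, partial correlations and BH-FDR."""

import numpy as np
import pandas as pd
import pytest

from refcoh.inference import (
    DesignMatrix,
    bh_fdr,
    build_design,
    compare_models,
    deviance_gof,
    gee_gaussian_exchangeable,
    poisson_glm_offset,
    spearman_partial,
)
from refcoh.simulate import simulate_clustered_outcome


def _two_group_fixture():
    df = pd.DataFrame({"group": ["NC", "NC", "FEP"]})
    design = build_design(df)
    counts = np.array([10, 20, 30])
    exposure = np.log(np.array([100.0, 200.0, 100.0]))
    return counts, exposure, design


class TestPoissonOffset:
    def test_two_group_closed_form(self):
        counts, exposure, design = _two_group_fixture()
        fit = poisson_glm_offset(counts, exposure, design)
        assert fit.B[0] == pytest.approx(np.log(0.1), abs=1e-8)
        assert fit.B[1] == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.converged

    def test_offset_rescaling_shifts_only_intercept(self):
        counts, exposure, design = _two_group_fixture()
        c = 7.0
        fit = poisson_glm_offset(counts, exposure, design)
        fit_scaled = poisson_glm_offset(counts, exposure + np.log(c), design)
        assert fit_scaled.B[0] == pytest.approx(fit.B[0] - np.log(c), abs=1e-8)
        assert fit_scaled.B[1] == pytest.approx(fit.B[1], abs=1e-8)

    def test_score_equations_hold_at_solution(self, rng):
        n = 200
        df = pd.DataFrame(
            {"group": rng.choice(["NC", "FEP", "UHR"], n), "age": rng.normal(30, 5, n)}
        )
        design = build_design(df, covariates=["age"])
        words = rng.integers(100, 400, n)
        counts = rng.poisson(0.05 * words)
        fit = poisson_glm_offset(counts, np.log(words.astype(float)), design)
        mu = np.exp(design.X @ fit.B + np.log(words))
        score = design.X.T @ (counts - mu)
        assert np.max(np.abs(score)) < 1e-6

    def test_all_zero_group_flags_separation(self):
        df = pd.DataFrame({"group": ["NC"] * 5 + ["FEP"] * 5})
        design = build_design(df)
        counts = np.array([5, 7, 6, 4, 8, 0, 0, 0, 0, 0])
        exposure = np.log(np.full(10, 100.0))
        fit = poisson_glm_offset(counts, exposure, design)
        assert "group[FEP]" in fit.separation
        assert fit.B[1] < -10

    def test_non_integer_counts_rejected(self):
        counts, exposure, design = _two_group_fixture()
        with pytest.raises(ValueError, match="integer"):
            poisson_glm_offset(np.array([1.5, 2, 3]), exposure, design)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X=X, columns=["Intercept", "x", "x2"])

    def test_simulation_recovers_rate_ratio(self, rng):
        # 50 units per group, true ratio 0.7; average over replicates
        ratios = []
        for _ in range(60):
            words = rng.integers(150, 350, 100)
            rate = np.where(np.arange(100) < 50, 0.05, 0.05 * 0.7)
            counts = rng.poisson(rate * words)
            df = pd.DataFrame({"group": ["NC"] * 50 + ["FEP"] * 50})
            fit = poisson_glm_offset(
                counts, np.log(words.astype(float)), build_design(df)
            )
            ratios.append(np.exp(fit.B[1]))
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.02)


class TestCompareModels:
    def _fits(self, rng, beta_age=0.0, n=400):
        words = rng.integers(100, 300, n)
        age = rng.normal(0, 1, n)
        counts = rng.poisson(0.05 * words * np.exp(beta_age * age))
        df = pd.DataFrame({"group": ["NC"] * n, "age": age})
        full = poisson_glm_offset(
            counts, np.log(words.astype(float)), build_design(df, covariates=["age"])
        )
        reduced = poisson_glm_offset(
            counts, np.log(words.astype(float)), build_design(df)
        )
        return full, reduced

    def test_identical_fits_lrt_zero(self, rng):
        full, _ = self._fits(rng)
        res = compare_models(full, full)
        assert res["lrt_stat"] == pytest.approx(0.0, abs=1e-9)
        assert res["df"] == 0 and res["delta_aic"] == pytest.approx(0.0, abs=1e-9)

    def test_null_covariate_lrt_is_chi2(self, rng):
        rejections = sum(
            compare_models(*self._fits(rng))["p"] < 0.05 for _ in range(60)
        )
        assert rejections <= 9  # nominal 5% of 60

    def test_strong_covariate_favoured_by_aic(self, rng):
        full, reduced = self._fits(rng, beta_age=0.3)
        res = compare_models(full, reduced)
        assert res["delta_aic"] > 10 and res["p"] < 1e-6

    def test_non_nested_rejected(self, rng):
        full, reduced = self._fits(rng)
        with pytest.raises(ValueError, match="nested"):
            compare_models(reduced, full)


class TestGEE:
    def test_singleton_clusters_equal_ols(self, rng):
        n = 60
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), x]), columns=["Intercept", "x"]
        )
        fit = gee_gaussian_exchangeable(y, design, np.arange(n))
        ols = np.linalg.lstsq(design.X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.B, ols, atol=1e-8)

    def test_recovers_slope_and_working_correlation(self):
        y, X, cl = simulate_clustered_outcome(
            200, 4, beta=0.09, rho=0.4, sigma=0.5, seed=9
        )
        design = DesignMatrix(X=X, columns=["Intercept", "x"])
        fit = gee_gaussian_exchangeable(y, design, cl)
        assert fit.B[1] == pytest.approx(0.09, abs=0.05)
        assert fit.rho == pytest.approx(0.4, abs=0.05)
        assert fit.n_clusters == 200

    def test_sandwich_se_invariant_to_cluster_relabeling(self):
        y, X, cl = simulate_clustered_outcome(50, 4, beta=0.1, rho=0.3, sigma=1.0, seed=2)
        design = DesignMatrix(X=X, columns=["Intercept", "x"])
        fit1 = gee_gaussian_exchangeable(y, design, cl)
        relabeled = (cl * 977) % 1009  # bijective on 0..49
        fit2 = gee_gaussian_exchangeable(y, design, relabeled)
        np.testing.assert_allclose(fit1.se, fit2.se, rtol=1e-8)

    def test_too_few_clusters_rejected(self):
        design = DesignMatrix(X=np.ones((4, 1)), columns=["Intercept"])
        with pytest.raises(ValueError, match="clusters"):
            gee_gaussian_exchangeable(np.ones(4), design, np.zeros(4))


class TestDevianceGof:
    def test_perfect_fit_zero_deviance(self):
        y, X, cl = simulate_clustered_outcome(30, 2, beta=0.5, rho=0.0, sigma=1.0, seed=1)
        design = DesignMatrix(X=X, columns=["Intercept", "x"])
        fit = gee_gaussian_exchangeable(X @ np.array([1.0, 2.0]), design, cl)
        res = deviance_gof(fit, scale=1.0)
        assert res["deviance"] == pytest.approx(0.0, abs=1e-12)

    def test_correct_model_deviance_per_df_near_one(self):
        y, X, cl = simulate_clustered_outcome(300, 2, beta=0.0, rho=0.0, sigma=1.0, seed=4)
        design = DesignMatrix(X=X, columns=["Intercept", "x"])
        fit = gee_gaussian_exchangeable(y, design, cl)
        res = deviance_gof(fit, scale=1.0)  # known noise variance
        assert res["deviance_per_df"] == pytest.approx(1.0, abs=0.15)

    def test_misspecified_mean_inflates_deviance(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 3.0 * x**2 + rng.standard_normal(n)  # quadratic truth, linear model
        design = DesignMatrix(
            X=np.column_stack([np.ones(n), x]), columns=["Intercept", "x"]
        )
        fit = gee_gaussian_exchangeable(y, design, np.arange(n) // 2)
        res = deviance_gof(fit, scale=1.0)
        assert res["deviance_per_df"] > 5


class TestSpearmanPartial:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        assert spearman_partial(x, x).rho == pytest.approx(1.0)

    def test_shared_covariate_explains_association(self, rng):
        z = rng.standard_normal(300)
        res = spearman_partial(2 * z, -3 * z, z)
        assert abs(res.rho) < 1e-6

    def test_monotone_confounder_with_noise(self, rng):
        z = rng.standard_normal(500)
        x = z + 0.3 * rng.standard_normal(500)
        y = z + 0.3 * rng.standard_normal(500)
        raw = spearman_partial(x, y)
        partial = spearman_partial(x, y, z)
        assert raw.rho > 0.7
        assert abs(partial.rho) < 0.2

    def test_independent_null_p_uniform(self, rng):
        pvals = [
            spearman_partial(rng.standard_normal(100), rng.standard_normal(100)).p
            for _ in range(200)
        ]
        assert 0.01 < np.mean(np.asarray(pvals) < 0.2) < 0.35

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x = rng.standard_normal(80)
        y = 0.4 * x + rng.standard_normal(80)
        z = rng.standard_normal((80, 2))
        ours = spearman_partial(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"], method="spearman")
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-4)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_partial(np.ones(10), np.arange(10.0))


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHFDR:
    def test_worked_vectors(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]).q, [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_fdr([0.005, 0.5]).q, [0.01, 0.5])
        np.testing.assert_allclose(bh_fdr([0.3]).q, [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert np.all(bh_fdr(p).q >= p - 1e-15)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p).q, brute_force_bh(p), atol=1e-12)
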