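"""Cohort statistics tests: E:I ratio, paired tests, correlations, the mixed
model, R^2 decomposition, VIF, and power simulation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from eihurst.cohort import (
    EIHurstLMM,
    LmmResult,
    _design_matrix,
    ei_ratio,
    fit_lmm,
    paired_condition_test,
    pearson_corr,
    power_simulation,
    r2_nakagawa,
    vif,
)
from eihurst.synthgen import CohortSpec, generate_cohort_table


class TestEiRatio:
    def test_basic(self):
        assert ei_ratio(10, 5) == 2.0
        assert ei_ratio(9.84, 5.48) == pytest.approx(9.84 / 5.48)
        assert ei_ratio(3.3, 3.3) == 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            ei_ratio(-1, 5)
        with pytest.raises(ValueError):
            ei_ratio(5, 0)


class TestPairedTest:
    def test_constant_shift_degenerate(self):
        rest = np.array([0.9, 1.0, 1.1, 1.2])
        with pytest.raises(ValueError, match="zero variance"):
            paired_condition_test(rest, rest + 0.07)

    def test_three_pair_closed_form(self):
        # hand-computed paired t on diffs {1.01, 0.99, 1.0}
        rest = np.array([1.0, 2.0, 3.0])
        movie = np.array([2.0, 3.0, 4.0]) + np.array([0.01, -0.01, 0.0])
        out = paired_condition_test(rest, movie)
        diffs = movie - rest
        sd = diffs.std(ddof=1)
        t_ref = diffs.mean() / (sd / np.sqrt(3))
        assert out["t"] == pytest.approx(t_ref, abs=1e-12)
        assert out["df"] == 2
        from scipy import stats
        assert out["p"] == pytest.approx(2 * stats.t.sf(abs(t_ref), 2), abs=1e-12)
        assert out["cohens_d"] == pytest.approx(diffs.mean() / sd, abs=1e-12)

    def test_pairing_invariance(self, rng):
        rest = rng.normal(1.0, 0.1, 8)
        movie = rest + rng.normal(0.05, 0.02, 8)
        perm = rng.permutation(8)
        a = paired_condition_test(rest, movie)
        b = paired_condition_test(rest[perm], movie[perm])
        assert a["t"] == pytest.approx(b["t"])
        assert a["p"] == pytest.approx(b["p"])


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(5.0)
        assert pearson_corr(x, 2 * x + 1)["r"] == pytest.approx(1.0)
        assert pearson_corr(x, -x)["r"] == pytest.approx(-1.0)

    def test_brute_force_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.5, 3.0, 5.0, 4.0])
        r_ref = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_corr(x, y)["r"] == pytest.approx(r_ref, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestFitLmm:
    def test_ols_equivalence_at_boundary(self):
        """With zero generative random-intercept variance, REML boundary fits
        reproduce OLS coefficients; the boundary is reached in at least one
        pre-fixed replicate."""
        n_boundary = 0
        for seed in range(6):
            spec = CohortSpec(
                n_subjects=30, subject_intercept_sd=0.0, beta_ei=0.07, seed=seed
            )
            table = generate_cohort_table(spec)
            fit = fit_lmm(table)
            X, _ = _design_matrix(table)
            ols = sm.OLS(table["hurst"].to_numpy(), X).fit()
            if fit.random_intercept_var < 1e-8 * fit.residual_var:
                n_boundary += 1
                np.testing.assert_allclose(
                    fit.fixed_effects["estimate"].to_numpy(), ols.params, atol=1e-4
                )
        assert n_boundary >= 1

    def test_parameter_recovery(self):
        # estimates within 2 SE of the generative coefficients at n = 200
        spec = CohortSpec(
            n_subjects=200,
            hurst_intercept=1.3,
            beta_rest=-0.07,
            beta_ei=0.07,
            seed=11,
        )
        fit = fit_lmm(generate_cohort_table(spec))
        fe = fit.fixed_effects
        for term, truth in [("intercept", 1.3), ("condition_rest", -0.07), ("ei", 0.07)]:
            assert abs(fe.loc[term, "estimate"] - truth) < 2 * fe.loc[term, "std_error"]
        # covariates have zero generative effect
        for term in ["mean_fd_mm", "fwhm_slaser", "fwhm_mega"]:
            assert abs(fe.loc[term, "estimate"]) < 3 * fe.loc[term, "std_error"]

    def test_balanced_replication_invariance(self):
        # Exact invariance under balanced duplication holds for ML; the REML
        # determinant correction does not scale with n, so the variance-ratio
        # estimate (and hence the GLS coefficients) shifts at O(1/n).
        table = generate_cohort_table(CohortSpec(n_subjects=12, seed=2))
        dup = table.copy()
        dup["subject_id"] = dup["subject_id"] + "_b"
        fit_a = fit_lmm(table)
        fit_b = fit_lmm(pd.concat([table, dup], ignore_index=True))
        np.testing.assert_allclose(
            fit_a.fixed_effects["estimate"], fit_b.fixed_effects["estimate"], atol=5e-3
        )

    def test_too_few_subjects(self):
        table = generate_cohort_table(CohortSpec(n_subjects=4, seed=0))
        with pytest.raises(ValueError, match="6 subjects"):
            fit_lmm(table)

    def test_collinear_design_named(self):
        table = generate_cohort_table(CohortSpec(n_subjects=12, seed=3))
        table["fwhm_mega"] = table["fwhm_slaser"]
        with pytest.raises(ValueError, match="fwhm"):
            fit_lmm(table)

    def test_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            fit_lmm(pd.DataFrame({"subject_id": ["a"], "condition": ["rest"]}))


class TestR2:
    def test_marginal_le_conditional(self):
        fit = fit_lmm(generate_cohort_table(CohortSpec(seed=5)))
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1

    def test_null_fixed_effects_marginal_zero(self):
        # zero coefficients on every predictor -> no fixed-effect variance
        table = generate_cohort_table(CohortSpec(seed=7))
        fit = fit_lmm(table)
        null_fit = LmmResult(
            fixed_effects=fit.fixed_effects.assign(
                estimate=[1.0] + [0.0] * (len(fit.fixed_effects) - 1)
            ),
            random_intercept_var=0.01,
            residual_var=0.003,
            r2_marginal=np.nan,
            r2_conditional=np.nan,
            n_obs=fit.n_obs,
            n_subjects=fit.n_subjects,
            converged=True,
        )
        r2m, r2c = r2_nakagawa(null_fit, table)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert r2c == pytest.approx(0.01 / 0.013, abs=1e-9)

    def test_known_variance_partition(self):
        # fixed 0.2 / intercept 0.5 / residual 0.3 -> (~0.2, ~0.7) at large n
        rng = np.random.default_rng(31)
        n = 400
        rows = []
        beta = np.sqrt(0.2)  # predictor ~ N(0,1) gives fixed variance 0.2
        for i in range(n):
            u = rng.normal(0, np.sqrt(0.5))
            for cond in ("rest", "movie"):
                x = rng.normal()
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "condition": cond,
                        "ei": x,
                        "hurst": beta * x + u + rng.normal(0, np.sqrt(0.3)),
                        "glx_mM": 10.0,
                        "gaba_mM": 5.0,
                        "mean_fd_mm": rng.normal(),
                        "fwhm_slaser": rng.normal(),
                        "fwhm_mega": rng.normal(),
                        "freq_shift_slaser": rng.normal(),
                        "freq_shift_mega": rng.normal(),
                    }
                )
        fit = fit_lmm(pd.DataFrame(rows))
        assert fit.r2_marginal == pytest.approx(0.2, abs=0.05)
        assert fit.r2_conditional == pytest.approx(0.7, abs=0.05)


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(1)
        n = 64
        a = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        b = np.tile([1.0, -1.0], n // 2)
        df = pd.DataFrame({"a": a, "b": b, "c": rng.permutation(a) * b})
        out = vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=1e-9)
        assert out["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_infinite(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        with pytest.warns(UserWarning, match="collinear"):
            out = vif(df, ["a", "b"])
        assert np.isinf(out["a"])

    def test_known_correlation_closed_form(self):
        # r = 0.8 exactly -> VIF = 1/(1 - 0.64) = 2.777...
        n = 100
        rng = np.random.default_rng(4)
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        # orthogonalise then recombine for an exact sample correlation
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        y = 0.8 * x + np.sqrt(1 - 0.64) * e
        out = vif(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        assert out["x"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)


class TestPower:
    def test_seed_determinism(self):
        spec = CohortSpec(seed=1)
        a = power_simulation(spec, 0.14, n_sims=20, seed=9)
        b = power_simulation(spec, 0.14, n_sims=20, seed=9)
        assert a == b

    def test_result_invariants(self):
        spec = CohortSpec(seed=1)
        r = power_simulation(spec, 0.21, n_sims=30, seed=5)
        assert 0 <= r.ci95[0] <= r.power <= r.ci95[1] <= 1
        assert r.n_simulations + r.n_failed == 30


class TestModelObject:
    def test_summary_and_dict(self):
        res = EIHurstLMM.from_dataframe(generate_cohort_table(CohortSpec(seed=8))).fit()
        text = res.summary()
        assert "Linear mixed-effects" in text and "condition_rest" in text
        d = res.to_dict()
        assert set(d["fixed_effects"]) >= {"intercept", "ei", "condition_rest"}
        assert d["r2_marginal"] <= d["r2_conditional"]

    def test_tsv_roundtrip(self, tmp_path):
        table = generate_cohort_table(CohortSpec(seed=8))
        p = tmp_path / "cohort.tsv"
        table.to_csv(p, sep="\t", index=False)
        res = EIHurstLMM.from_tsv(p).fit()
        ref = EIHurstLMM.from_dataframe(table).fit()
        np.testing.assert_allclose(
            res.fixed_effects["estimate"], ref.fixed_effects["estimate"], atol=1e-10
        )
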