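"""Association-engine checks: the OLS/REML cores against statsmodels, the
model-level contracts, the scan enumeration, and multiple testing."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from telosperm.associate import (InsufficientDataError, ModelError,
                                 apply_multiple_testing, fit_linear,
                                 fit_plate_mixed, random_intercept_reml,
                                 run_scan, wald_ols, AssociationRecord)
from telosperm.pipeline import run_pipeline_on_cohort
from telosperm.simulate import CohortConfig, simulate_cohort


def _design(n=400, seed=0, group_sd=0.4, n_groups=20):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         rng.integers(0, 2, n).astype(float)])
    y = X @ [1.0, 0.3, 0.2] + rng.normal(0, 0.7, n)
    if group_sd > 0:
        y = y + rng.normal(0, group_sd, n_groups)[g]
    return y, X, g


class TestEstimationCores:
    def test_ols_matches_statsmodels_exactly(self):
        y, X, _ = _design(group_sd=0.0)
        mine = wald_ols(y, X, ["i", "x", "z"])
        ref = sm.OLS(y, X).fit()
        assert np.allclose(mine.beta, ref.params, atol=1e-12)
        assert np.allclose(mine.se, ref.bse, atol=1e-12)
        assert np.allclose(mine.p_values, ref.pvalues, atol=1e-12)
        ci = ref.conf_int()
        assert np.allclose(mine.ci, ci, atol=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_reml_matches_statsmodels_mixedlm(self, seed):
        y, X, g = _design(seed=seed)
        mine = random_intercept_reml(y, X, g, ["i", "x", "z"])
        ref = sm.MixedLM(y, X, groups=g).fit(reml=True)
        assert np.allclose(mine.beta, ref.params[:3], atol=1e-6)
        assert np.allclose(mine.se, ref.bse[:3], atol=1e-4)
        assert mine.lam * mine.sigma2 == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4)

    def test_degenerate_group_variance_reduces_to_ols(self):
        # within-group-centered noise has zero between-group variance in
        # sample, so the REML variance estimate hits the zero boundary and
        # the fit must coincide with OLS exactly
        rng = np.random.default_rng(4)
        n, n_groups = 400, 20
        g = np.repeat(np.arange(n_groups), n // n_groups)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        e = rng.normal(0, 0.7, n)
        e -= np.repeat(np.bincount(g, weights=e) / (n // n_groups), n // n_groups)
        y = X @ [1.0, 0.3] + e
        mixed = random_intercept_reml(y, X, g, ["i", "x"])
        ols = wald_ols(y, X, ["i", "x"])
        assert mixed.lam == 0.0
        assert np.allclose(mixed.beta, ols.beta, atol=1e-12)

    def test_true_zero_group_variance_estimates_close_to_ols(self):
        # with a truly null random effect the REML estimate may sit just
        # above the boundary; estimates then agree only stochastically
        y, X, g = _design(group_sd=0.0, seed=4)
        mixed = random_intercept_reml(y, X, g, ["i", "x", "z"])
        ols = wald_ols(y, X, ["i", "x", "z"])
        assert np.allclose(mixed.beta, ols.beta, atol=0.05)

    def test_constant_term_raises(self):
        y, X, _ = _design(group_sd=0.0)
        X = X.copy()
        X[:, 2] = 1.0
        with pytest.raises(ModelError, match="constant|collinear"):
            wald_ols(y, X, ["i", "x", "z"])

    def test_collinear_design_raises(self):
        y, X, _ = _design(group_sd=0.0)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(ModelError, match="collinear"):
            wald_ols(y, X2, ["i", "x", "z", "x_dup"])


class TestModelInterface:
    def test_parameter_recovery_within_ci(self):
        rng = np.random.default_rng(7)
        n = 2000
        data = {
            "x": rng.normal(size=n),
            "age": rng.uniform(18, 59, n),
            "smoker": rng.integers(0, 2, n).astype(float),
        }
        data["y"] = 0.5 * data["x"] + 0.1 * data["age"] + \
            rng.normal(0, 1.0, n)
        rec = fit_linear(data, outcome="y", exposure_cols=["x"],
                         exposure="x", form="linear", family="stl")[0]
        assert rec.ci_low <= 0.5 <= rec.ci_high
        assert rec.n == n

    def test_null_exposure_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        n, reps = 120, 500
        hits = 0
        for _ in range(reps):
            data = {
                "x": rng.normal(size=n),
                "age": rng.uniform(18, 59, n),
                "smoker": rng.integers(0, 2, n).astype(float),
                "y": rng.normal(size=n),
            }
            rec = fit_linear(data, outcome="y", exposure_cols=["x"],
                             exposure="x", form="linear", family="stl")[0]
            hits += rec.p_value < 0.05
        assert abs(hits / reps - 0.05) < 0.025

    def test_duplicated_exposure_as_covariate_collinear(self):
        rng = np.random.default_rng(13)
        n = 100
        x = rng.normal(size=n)
        data = {"x": x, "age": x, "smoker": rng.integers(0, 2, n).astype(float),
                "y": rng.normal(size=n)}
        with pytest.raises(ModelError):
            fit_linear(data, outcome="y", exposure_cols=["x"], exposure="x",
                       form="linear", family="stl")

    def test_insufficient_cases_raise(self):
        data = {"x": np.arange(5.0), "age": np.arange(5.0) + 30,
                "smoker": np.array([0, 1, 0, 1, 0.0]), "y": np.arange(5.0)}
        with pytest.raises(InsufficientDataError):
            fit_linear(data, outcome="y", exposure_cols=["x"], exposure="x",
                       form="linear", family="stl")

    def test_mixed_zero_plate_variance_matches_ols(self):
        rng = np.random.default_rng(17)
        n = 500
        data = {
            "x": rng.normal(size=n),
            "age": rng.uniform(18, 59, n),
            "smoker": rng.integers(0, 2, n).astype(float),
            "plate": rng.integers(1, 11, n).astype(float),
        }
        data["y"] = 0.3 * data["x"] + rng.normal(0, 1, n)  # no plate effect
        mixed = fit_plate_mixed(data, outcome="y", exposure_cols=["x"],
                                exposure="x", form="linear", family="snp")[0]
        ols = fit_linear(data, outcome="y", exposure_cols=["x"],
                         exposure="x", form="linear", family="snp")[0]
        assert mixed.coefficient == pytest.approx(ols.coefficient, abs=1e-5)

    def test_single_plate_falls_back_to_ols_with_warning(self):
        rng = np.random.default_rng(19)
        n = 100
        data = {
            "x": rng.normal(size=n), "age": rng.uniform(18, 59, n),
            "smoker": rng.integers(0, 2, n).astype(float),
            "plate": np.ones(n), "y": rng.normal(size=n),
        }
        with pytest.warns(UserWarning, match="single plate"):
            rec = fit_plate_mixed(data, outcome="y", exposure_cols=["x"],
                                  exposure="x", form="linear", family="snp")[0]
        assert rec.plate_handling == "ols_fallback"


class TestMultipleTesting:
    def _rec(self, p):
        return AssociationRecord(outcome="o", exposure="e", form="additive",
                                 term="t", family="snp", n=100,
                                 coefficient=0.0, ci_low=-1, ci_high=1,
                                 p_value=p)

    def test_threshold_is_0_0015_at_printed_precision(self):
        recs = apply_multiple_testing([self._rec(0.5)], alpha=0.05, m=33)
        assert round(recs[0].threshold, 4) == 0.0015

    def test_p_009_not_significant_after_correction(self):
        recs = apply_multiple_testing([self._rec(0.009)], alpha=0.05, m=33)
        assert recs[0].significant is False

    def test_m_one_reduces_to_nominal(self):
        recs = apply_multiple_testing([self._rec(0.03)], alpha=0.05, m=1)
        assert recs[0].significant is True


@pytest.fixture(scope="module")
def scan():
    cohort = simulate_cohort(CohortConfig(n_subjects=250, seed=41,
                                          n_plates=8))
    res = run_pipeline_on_cohort(cohort)
    return cohort, res


class TestRunScan:

    def test_record_count_matches_design_enumeration(self, scan):
        cohort, res = scan
        r = res.results
        from telosperm.genoqc import codominant_contrasts
        contrasts = codominant_contrasts(res.kept_genotypes, cohort.panel)
        n_outcomes = 11          # 9 semen parameters + ABCD + ABCD_mot
        n_out_snp = n_outcomes + 1   # + log STL
        # STL: linear + 4 quintile contrasts per sperm outcome
        expected = n_outcomes * 5
        # scores: 2 scores x (1 + 4) x (sperm outcomes + log STL)
        expected += 2 * 5 * n_out_snp
        # SNPs: additive + per-SNP codominant contrast count
        for snp in cohort.panel:
            k = len(contrasts[snp.snp_id].columns)
            expected += (1 + k) * n_out_snp
        assert res.skips == []
        assert len(r) == expected

    def test_snp_records_carry_bonferroni_threshold(self, scan):
        _, res = scan
        r = res.results
        snp = r[r["family"] == "snp"]
        assert (snp["threshold"].round(4) == 0.0015).all()
        other = r[r["family"] != "snp"]
        assert (other["threshold"] == 0.05).all()

    def test_log_stl_models_use_plate_random_effect(self, scan):
        _, res = scan
        r = res.results
        stl_out = r[r["outcome"] == "log_stl"]
        assert (stl_out["plate_handling"] == "random_effect").all()
        sperm_out = r[r["outcome"] == "progressive_motility"]
        assert (sperm_out["plate_handling"] == "none").all()

    def test_two_class_snp_emits_single_codominant_contrast(self):
        # force a SNP to two classes by using a rare allele and small n
        cohort = simulate_cohort(CohortConfig(n_subjects=120, seed=43,
                                              n_plates=4))
        res = run_pipeline_on_cohort(cohort)
        r = res.results
        counts = r[(r["form"] == "codominant")
                   & (r["outcome"] == "concentration")]
        by_snp = counts.groupby("exposure").size()
        from telosperm.genoqc import codominant_contrasts
        expected = {s.snp_id: len(codominant_contrasts(
            res.kept_genotypes, [s])[s.snp_id].columns)
            for s in cohort.panel}
        for rsid, k in by_snp.items():
            assert k == expected[rsid]

    def test_quintile_and_linear_trends_agree_on_monotone_effect(self):
        cfg = CohortConfig(n_subjects=400, seed=47, n_plates=8,
                           beta_sperm_per_logTL=40.0, sigma_tl=0.4)
        res = run_pipeline_on_cohort(simulate_cohort(cfg))
        r = res.results
        lin = r[(r["exposure"] == "log_stl_residual") & (r["form"] == "linear")
                & (r["outcome"] == "concentration")].iloc[0]
        q5 = r[(r["exposure"] == "log_stl_residual")
               & (r["form"] == "quintile")
               & (r["outcome"] == "concentration")
               & (r["term"].str.startswith("5th"))].iloc[0]
        assert lin.coefficient > 0
        assert np.sign(q5.coefficient) == np.sign(lin.coefficient)

    def test_nothing_dropped_silently(self, scan):
        _, res = scan
        # every attempted model is either a record or a logged skip
        assert isinstance(res.skips, list)
        for s in res.skips:
            assert {"outcome", "exposure", "form", "reason"} <= set(s)
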