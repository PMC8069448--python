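"""QC checks: call-rate filtering, Hardy-Weinberg testing, duplicate
concordance, and the additive/codominant encodings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telosperm.genoqc import (GenotypeDataError, codominant_contrasts,
                              duplicate_concordance, encode_additive,
                              genotype_counts, hwe_exact_test, hwe_test,
                              normalize_call, run_qc,
                              subject_call_rate_filter, subject_call_rates)
from telosperm.panel import SnpDefinition
from telosperm.simulate import CohortConfig, simulate_cohort


def _frame_with_missing(n_missing_per_subject, n_snps=11):
    """One subject per entry; entry = number of missing SNPs."""
    rows = {}
    for i, k in enumerate(n_missing_per_subject):
        calls = ["C/C"] * (n_snps - k) + [None] * k
        rows[f"s{i}"] = calls
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"rs{j}" for j in range(n_snps)])


class TestCallRateFilter:
    def test_nine_of_eleven_kept_eight_discarded(self):
        g = _frame_with_missing([2, 3])  # 9/11 = 81.8%, 8/11 = 72.7%
        kept, discarded = subject_call_rate_filter(g, 0.80)
        assert list(kept.index) == ["s0"]
        assert discarded == ["s1"]

    def test_engineered_missingness_matches_brute_force_tally(self):
        cfg = CohortConfig(n_subjects=400, seed=13, bad_subject_rate=0.1,
                           bad_missing_rate=0.6)
        cohort = simulate_cohort(cfg)
        g = cohort.genotypes
        kept, discarded = subject_call_rate_filter(g, 0.80)
        # oracle: count non-missing calls row by row
        expected = [sid for sid, row in g.iterrows()
                    if sum(c is not None and not (isinstance(c, float))
                           for c in row) / g.shape[1] < 0.80]
        assert sorted(discarded) == sorted(expected)
        assert len(discarded) > 0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            subject_call_rates(pd.DataFrame())


class TestHweTest:
    def test_exact_hwe_proportions_give_zero_chi2(self):
        chi2, p = hwe_test(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_expected_count_oracle(self):
        counts = np.array([30, 50, 20])
        n = counts.sum()
        q = (counts[1] + 2 * counts[2]) / (2 * n)
        expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        oracle = float(np.sum((counts - expected) ** 2 / expected))
        chi2, p = hwe_test(30, 50, 20)
        assert chi2 == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(oracle, 1), rel=1e-12)

    def test_complete_heterozygote_deficit_gives_chi2_n(self):
        chi2, p = hwe_test(50, 0, 50)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-10

    def test_monomorphic_not_applicable(self):
        chi2, p = hwe_test(100, 0, 0)
        assert np.isnan(chi2) and np.isnan(p)

    def test_pvalues_uniform_under_hwe(self):
        # p-values across HWE-simulated genotype draws should be ~U(0,1)
        rng = np.random.default_rng(17)
        q = 0.3
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        pvals = []
        for _ in range(1000):
            counts = rng.multinomial(400, probs)
            p = hwe_test(*counts)[1]
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_exact_test_matches_random_pairing_oracle(self):
        # conditional on allele counts, HWE is equivalent to random pairing
        # of the allele pool: simulate that directly as the oracle
        n_maj_hom, n_het, n_min_hom = 12, 12, 6
        n = n_maj_hom + n_het + n_min_hom
        alleles = np.array([0] * (2 * n_maj_hom + n_het)
                           + [1] * (2 * n_min_hom + n_het))
        rng = np.random.default_rng(41)
        het_counts = np.zeros(2 * n + 1)
        reps = 40_000
        for _ in range(reps):
            rng.shuffle(alleles)
            pairs = alleles.reshape(n, 2)
            het_counts[int((pairs[:, 0] != pairs[:, 1]).sum())] += 1
        probs = het_counts / reps
        p_obs = probs[n_het]
        oracle = probs[probs <= p_obs + 1e-9].sum()
        p_exact = hwe_exact_test(n_maj_hom, n_het, n_min_hom)
        assert abs(p_exact - oracle) < 0.02


class TestDuplicateConcordance:
    def test_identical_rows_fully_concordant(self):
        calls = ["C/C", "C/A", "A/A"] * 3
        assert duplicate_concordance([(calls, list(calls))]) == 1.0

    def test_one_discordant_of_eleven(self):
        a = ["C/C"] * 11
        b = ["C/C"] * 10 + ["C/A"]
        assert duplicate_concordance([(a, b)]) == pytest.approx(10 / 11)

    def test_unordered_calls_compare_equal(self):
        assert duplicate_concordance([(["C/A"], ["A/C"])]) == 1.0

    def test_simulated_flip_rate_near_99pct(self):
        rng = np.random.default_rng(23)
        pairs = []
        n_pairs, n_snps, flip = 50, 11, 0.01
        for _ in range(n_pairs):
            a = ["C/C"] * n_snps
            b = ["C/C" if rng.random() > flip else "C/A"
                 for _ in range(n_snps)]
            pairs.append((a, b))
        conc = duplicate_concordance(pairs)
        se = np.sqrt(0.99 * 0.01 / (n_pairs * n_snps))
        assert abs(conc - 0.99) < 4 * se


class TestEncodings:
    def test_additive_dosage_counts_effect_alleles(self, two_snp_panel,
                                                   genotype_frame):
        d = encode_additive(genotype_frame, two_snp_panel)
        # rs1 effect allele A: C/C->0, C/A->1, A/A->2
        assert list(d["rs1"][:3]) == [0, 1, 2]
        assert np.isnan(d["rs1"]["s4"])
        # rs2 effect allele T (major): T/T->2, G/T->1, G/G->0
        assert d["rs2"]["s1"] == 2 and d["rs2"]["s2"] == 1
        assert d["rs2"]["s4"] == 0

    def test_unordered_call_equivalence(self, two_snp_panel):
        g = pd.DataFrame({"rs1": ["A/C", "C/A"], "rs2": ["T/G", "G/T"]},
                         index=["x", "y"])
        d = encode_additive(g, two_snp_panel)
        assert (d.loc["x"] == d.loc["y"]).all()

    def test_unknown_allele_names_subject_and_snp(self, two_snp_panel):
        g = pd.DataFrame({"rs1": ["C/G"], "rs2": ["T/T"]}, index=["bad_subj"])
        with pytest.raises(GenotypeDataError, match="bad_subj.*rs1"):
            encode_additive(g, two_snp_panel)

    def test_codominant_two_class_snp_emits_single_contrast(self):
        snp = SnpDefinition("rs6772228", "PXK", "T", "A", "T", 0.04, 0.04)
        g = pd.DataFrame({"rs6772228": ["T/T", "T/A", "T/T", "T/A"]},
                         index=list("wxyz"))
        contrasts = codominant_contrasts(g, [snp])["rs6772228"]
        assert list(contrasts.columns) == ["T/A vs. T/T"]
        assert list(contrasts["T/A vs. T/T"]) == [0, 1, 0, 1]

    def test_codominant_reference_class_all_zero(self, two_snp_panel):
        g = pd.DataFrame({"rs1": ["C/C", "C/A", "A/A"],
                          "rs2": ["T/T", "T/T", "T/T"]}, index=list("abc"))
        c = codominant_contrasts(g, two_snp_panel)
        assert (c["rs1"].loc["a"] == 0).all()
        assert c["rs2"].empty  # only the reference class present

    def test_codominant_indicator_sums_equal_class_counts(self, panel,
                                                          small_cohort):
        g = small_cohort.genotypes
        contrasts = codominant_contrasts(g, panel)
        for snp in panel:
            counts = genotype_counts(g[snp.snp_id], snp)
            sub = contrasts[snp.snp_id]
            for cls, label_part in ((1, f"{snp.major_allele}/{snp.minor_allele}"),
                                    (2, f"{snp.minor_allele}/{snp.minor_allele}")):
                cols = [c for c in sub.columns if c.startswith(label_part + " ")]
                if counts[cls] > 0:
                    assert len(cols) == 1
                    assert np.nansum(sub[cols[0]]) == counts[cls]
                else:
                    assert not cols


class TestQcProperties:
    def test_filter_and_encoding_commute(self, panel, small_cohort):
        g = small_cohort.genotypes
        kept, _ = subject_call_rate_filter(g, 0.80)
        a = encode_additive(kept, panel)
        b = encode_additive(g, panel).loc[kept.index]
        pd.testing.assert_frame_equal(a, b)

    def test_dosage_mean_tracks_effect_allele_frequency(self, panel):
        cohort = simulate_cohort(CohortConfig(n_subjects=5000, seed=29,
                                              missing_rate=0.0,
                                              bad_subject_rate=0.0))
        d = encode_additive(cohort.genotypes, panel)
        for snp in panel:
            eaf = snp.effect_allele_frequency
            se = np.sqrt(2 * eaf * (1 - eaf) / 5000) / 2
            assert abs(d[snp.snp_id].mean() / 2 - eaf) < 5 * se

    def test_run_qc_report_contents(self, panel, small_cohort):
        kept, dosages, report = run_qc(small_cohort.genotypes, panel)
        assert report.n_kept == len(kept) == len(dosages)
        assert set(report.hwe_results) == {s.snp_id for s in panel}
        assert set(np.unique(dosages.to_numpy()[np.isfinite(
            dosages.to_numpy())])) <= {0.0, 1.0, 2.0}
        d = report.to_dict()
        assert d["n_subjects"] == len(small_cohort.genotypes)
        assert 0.9 < d["mean_snp_call_rate"] <= 1.0


def test_normalize_call_variants():
    assert normalize_call("C/A") == normalize_call("A/C") == ("A", "C")
    assert normalize_call(None) is None
    assert normalize_call(float("nan")) is None
    assert normalize_call("") is None
    with pytest.raises(GenotypeDataError):
        normalize_call("CA")
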