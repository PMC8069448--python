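"""Repeated-simulation checks: null calibration and parameter recovery.

These are the statistical audits of the whole pipeline: under a null
generator the scan's nominal p < 0.05 rate must sit near 5% and the
Bonferroni-corrected SNP scan must almost never flag anything; with
injected effects the fitted 95% CIs must cover the generating values at
the nominal rate. The Bonferroni clause is checked per correction family
(the 33 SNP coefficients of one outcome), which is the guarantee the
0.05/33 threshold actually makes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .associate import fit_linear, fit_plate_mixed
from .genoqc import encode_additive, run_qc
from .pipeline import run_pipeline_on_cohort
from .qpcr import quantify
from .simulate import CohortConfig, simulate_cohort


@dataclass
class NullCalibration:
    n_replicates: int
    n_records: int
    nominal_rate: float                 # fraction of records with p < 0.05
    family_zero_rate: float             # fraction of (cohort, outcome)
    #                                     Bonferroni families with 0 hits
    cohorts_with_snp_hit: int           # cohorts with >= 1 flagged SNP record
    per_replicate_rates: list


def null_calibration(
    n_replicates: int = 500,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> NullCalibration:
    """Run the full pipeline on null cohorts and tally significance rates.

    The generator default config *is* the null: every telomere and sperm
    effect except the age trends can be zeroed via ``config``; here the
    null means ``beta_tl_per_effect_allele = 0`` and
    ``beta_sperm_per_logTL = 0`` with age trends also silenced so every
    exposure term is null by construction.
    """
    base = config if config is not None else CohortConfig()
    base = replace(base,
                   beta_tl_per_effect_allele=0.0,
                   beta_sperm_per_logTL=0.0,
                   age_betas={k: 0.0 for k in base.age_betas})
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    n_rec = n_p05 = 0
    fam_total = fam_zero = 0
    cohorts_with_hit = 0
    per_rep = []
    for ss in seeds:
        cfg = replace(base, seed=int(ss.generate_state(1)[0] % 2**31))
        res = run_pipeline_on_cohort(simulate_cohort(cfg))
        r = res.results
        # exposure terms only; every one is null by construction
        n_rec += len(r)
        n_p05 += int((r["p_value"] < 0.05).sum())
        per_rep.append(float((r["p_value"] < 0.05).mean()))
        snp = r[r["family"] == "snp"]
        hits_by_outcome = snp.groupby("outcome")["significant"].sum()
        fam_total += len(hits_by_outcome)
        fam_zero += int((hits_by_outcome == 0).sum())
        cohorts_with_hit += int(snp["significant"].any())
    return NullCalibration(
        n_replicates=n_replicates, n_records=n_rec,
        nominal_rate=n_p05 / n_rec,
        family_zero_rate=fam_zero / fam_total,
        cohorts_with_snp_hit=cohorts_with_hit,
        per_replicate_rates=per_rep)


@dataclass
class RecoveryResult:
    n_replicates: int
    tl_coverage: float        # CI coverage of beta_tl_per_effect_allele
    age_coverage: float       # CI coverage of the age slope on progressive motility
    tl_estimates: list
    age_estimates: list


def parameter_recovery(
    n_replicates: int = 500,
    seed: int = 0,
    beta_tl: float = 0.05,
    age_beta_progressive: float = -0.31,
    config: CohortConfig | None = None,
) -> RecoveryResult:
    """Coverage audit for two injected effects.

    Per replicate: (a) the per-effect-allele slope on measured log STL,
    fitted with the plate random intercept on the total dosage (the
    generating model), and (b) the age slope on progressive motility,
    fitted by the scan's adjusted OLS. Reports the fraction of replicates
    whose 95% CI covers the injected value.
    """
    base = config if config is not None else CohortConfig()
    base = replace(base, beta_tl_per_effect_allele=beta_tl)
    base.age_betas = dict(base.age_betas)
    base.age_betas["progressive_motility"] = age_beta_progressive
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    tl_cover = age_cover = 0
    tl_est, age_est = [], []
    for ss in seeds:
        cfg = replace(base, seed=int(ss.generate_state(1)[0] % 2**31))
        cohort = simulate_cohort(cfg)
        stl = quantify(cohort.ct)
        kept, dosages, _ = run_qc(cohort.genotypes, cohort.panel)
        # fully-genotyped subjects only: a partially-observed dosage sum is
        # an error-in-variables exposure and would attenuate the slope
        complete = encode_additive(kept, cohort.panel).dropna()
        total_dose = complete.sum(axis=1)
        df = cohort.subjects.merge(stl, on="subject_id")
        df["total_dosage"] = df["subject_id"].map(total_dose)
        cols = {c: df[c].to_numpy(float) for c in
                ("log_stl", "total_dosage", "age", "smoker", "plate")}
        rec = fit_plate_mixed(cols, outcome="log_stl",
                              exposure_cols=["total_dosage"],
                              exposure="total_dosage", form="linear",
                              family="score")[0]
        tl_est.append(rec.coefficient)
        tl_cover += int(rec.ci_low <= beta_tl <= rec.ci_high)

        pheno = cohort.subjects.merge(cohort.sperm, on="subject_id")
        cols = {c: pheno[c].to_numpy(float) for c in
                ("progressive_motility", "age", "smoker")}
        rec = fit_linear(cols, outcome="progressive_motility",
                         exposure_cols=["age"], exposure="age",
                         form="linear", family="stl", covariates=("smoker",))[0]
        age_est.append(rec.coefficient)
        age_cover += int(rec.ci_low <= age_beta_progressive <= rec.ci_high)
    return RecoveryResult(
        n_replicates=n_replicates,
        tl_coverage=tl_cover / n_replicates,
        age_coverage=age_cover / n_replicates,
        tl_estimates=tl_est, age_estimates=age_est)
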