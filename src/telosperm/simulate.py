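"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: HWE
genotypes at configurable MAFs with per-genotype (plus clustered
"degraded-DNA" subject) missingness, an additive allele effect on a latent
log telomere length, plate-structured triplicate qPCR Cts consistent with
that latent value, age-declining semen parameters, and a configurable
(default zero) telomere→sperm effect.

One master seed drives independently-seeded stages, so identical configs
produce byte-identical cohorts and individual stages are reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpDefinition, default_panel

#: Semen parameters produced by the generator (phenotypes.csv columns).
SPERM_PARAMETERS = (
    "concentration",            # 10^6 / mL
    "total_number",             # 10^6 / ejaculate
    "progressive_motility",     # %
    "nonprogressive_motility",  # %
    "total_motility",           # %
    "normal_morphology",        # %
    "normal_acrosome",          # %
    "normal_head",              # %
    "normal_flagellum",         # %
)

_PERCENT_PARAMS = frozenset(p for p in SPERM_PARAMETERS
                            if p not in ("concentration", "total_number"))

# Cohort-level parameter means/SDs (units above) and per-year age slopes.
# Means/SDs follow the marginal first moments of a consecutive andrology
# cohort; age slopes are literature-scale declines (motility and
# morphology fall with age, concentration is roughly flat).
_DEFAULT_MEANS = {
    "concentration": 55.4, "total_number": 180.0,
    "progressive_motility": 45.9, "nonprogressive_motility": 10.0,
    "total_motility": 48.3, "normal_morphology": 7.4,
    "normal_acrosome": 60.0, "normal_head": 55.0, "normal_flagellum": 60.0,
}
_DEFAULT_SDS = {
    "concentration": 49.0, "total_number": 140.0,
    "progressive_motility": 18.0, "nonprogressive_motility": 6.5,
    "total_motility": 16.5, "normal_morphology": 4.3,
    "normal_acrosome": 15.0, "normal_head": 16.0, "normal_flagellum": 16.0,
}
_DEFAULT_AGE_BETAS = {
    "concentration": 0.13, "total_number": -0.09,
    "progressive_motility": -0.31, "nonprogressive_motility": 0.04,
    "total_motility": -0.31, "normal_morphology": -0.10,
    "normal_acrosome": -0.07, "normal_head": -0.12, "normal_flagellum": -0.15,
}

#: 7-point 1:2 serial dilution of the standard curve, ng.
STANDARD_DILUTION_NG = tuple(20.0 / 2 ** k for k in range(7))
#: Input mass of each sample well, ng.
SAMPLE_INPUT_NG = 5.0
#: Subjects per 96-well plate: 6 sample wells each + 14 standard wells.
_SUBJECTS_PER_PLATE = 13


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Defaults describe the study conditions the analysis targets: 599
    subjects, ~2% background genotype missingness plus a small degraded-DNA
    fraction, no telomere→sperm effect (null), age 18–59, 32% smokers,
    plate-structured qPCR with near-doubling efficiencies.
    """

    n_subjects: int = 599
    seed: int = 0
    # genotypes
    missing_rate: float = 0.015
    bad_subject_rate: float = 0.025   # degraded-DNA subjects...
    bad_missing_rate: float = 0.5     # ...with this per-SNP missingness
    # latent telomere length (natural-log scale)
    tl_intercept: float = 0.0
    beta_tl_per_effect_allele: float = 0.0
    sigma_tl: float = 0.25
    # demographics
    age_range: tuple[float, float] = (18.0, 59.0)
    age_mean: float = 34.8
    age_sd: float = 7.5
    smoking_prevalence: float = 0.32
    # semen parameters
    age_betas: dict = field(default_factory=lambda: dict(_DEFAULT_AGE_BETAS))
    sperm_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sperm_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    beta_sperm_per_logTL: float = 0.0
    # qPCR
    n_plates: int | None = None       # None → ceil(n_subjects / 13)
    plate_sd: float = 0.3             # SD of per-(plate, target) Ct offsets
    ct_sd: float = 0.05               # replicate Ct noise SD
    efficiency_tel: float = 1.95
    efficiency_alb: float = 1.92
    tel_intercept_ct: float = 17.0    # Ct at 1 ng, Tel
    alb_intercept_ct: float = 27.0    # Ct at 1 ng, ALB

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("missing_rate", "bad_subject_rate", "bad_missing_rate",
                     "smoking_prevalence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("sigma_tl", "plate_sd", "ct_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("efficiency_tel", "efficiency_alb"):
            e = getattr(self, name)
            if not (1.0 < e <= 2.0):
                raise ValueError(f"{name}={e} outside (1, 2]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        if self.n_plates is not None and self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")

    @property
    def resolved_n_plates(self) -> int:
        if self.n_plates is not None:
            return self.n_plates
        return max(1, math.ceil(self.n_subjects / _SUBJECTS_PER_PLATE))


@dataclass
class Cohort:
    """All generated tables, keyed by a common subject_id set."""

    subjects: pd.DataFrame      # subject_id, age, smoker
    genotypes: pd.DataFrame     # index subject_id, one column per rsID
    latent_log_tl: pd.Series    # index subject_id
    ct: pd.DataFrame            # sample & standard wells
    sperm: pd.DataFrame         # subject_id + SPERM_PARAMETERS
    config: CohortConfig
    panel: list


def _subseeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _subject_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# stage generators

def simulate_genotypes(
    panel: list[SnpDefinition],
    n_subjects: int,
    missing_rate: float,
    seed: int,
    bad_subject_rate: float = 0.0,
    bad_missing_rate: float = 0.0,
) -> pd.DataFrame:
    """HWE genotypes for each panel SNP, with per-genotype missingness.

    Genotype classes are drawn at the Hardy–Weinberg proportions
    (p², 2pq, q²) of each SNP's MAF. A ``bad_subject_rate`` fraction of
    subjects additionally has every genotype missing independently with
    probability ``bad_missing_rate`` (clustered dropout, emulating
    degraded DNA samples that fail the call-rate filter).
    """
    if not panel:
        raise ValueError("empty panel")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for name, v in (("missing_rate", missing_rate),
                    ("bad_subject_rate", bad_subject_rate),
                    ("bad_missing_rate", bad_missing_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    ids = _subject_ids(n_subjects)
    bad = rng.random(n_subjects) < bad_subject_rate
    data = {}
    for snp in panel:
        q = snp.maf
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        n_minor = rng.choice(3, size=n_subjects, p=probs)
        calls = np.array([
            f"{snp.major_allele}/{snp.major_allele}",
            f"{snp.major_allele}/{snp.minor_allele}",
            f"{snp.minor_allele}/{snp.minor_allele}",
        ], dtype=object)[n_minor]
        miss_p = np.where(bad, bad_missing_rate, missing_rate)
        calls[rng.random(n_subjects) < miss_p] = None
        data[snp.snp_id] = calls
    return pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))


def _effect_dosages_for_generation(
    genotypes: pd.DataFrame, panel: list[SnpDefinition]
) -> np.ndarray:
    """Per-subject total effect-allele count; missing calls imputed at
    their population expectation (2 × effect-allele frequency) for
    generation purposes only."""
    total = np.zeros(len(genotypes))
    for snp in panel:
        calls = genotypes[snp.snp_id]
        dose = np.full(len(calls), 2.0 * snp.effect_allele_frequency)
        present = calls.notna().to_numpy()
        dose[present] = [c.split("/").count(snp.effect_allele)
                        for c in calls[present]]
        total += dose
    return total


def simulate_latent_tl(
    genotypes: pd.DataFrame,
    panel: list[SnpDefinition],
    beta_tl_per_effect_allele: float,
    sigma_tl: float,
    seed: int,
    intercept: float = 0.0,
) -> pd.Series:
    """Latent log telomere length: additive allele model plus Gaussian noise.

    latent = intercept + beta × (total effect-allele count) + N(0, sigma²).
    """
    rng = np.random.default_rng(seed)
    dosage_total = _effect_dosages_for_generation(genotypes, panel)
    latent = (intercept + beta_tl_per_effect_allele * dosage_total
              + rng.normal(0.0, sigma_tl, size=len(genotypes)))
    return pd.Series(latent, index=genotypes.index, name="latent_log_tl")


def simulate_ct_plates(
    latent_log_tl: pd.Series,
    config: CohortConfig,
    seed: int,
) -> pd.DataFrame:
    """Triplicate TEL/ALB sample wells plus per-plate standard curves.

    Sample wells: Ct = target intercept + plate offset − log(input)/log(E)
    − (latent log TL)/log(E) for TEL, + N(0, ct_sd); the latent term enters
    TEL wells only. Plate offsets are drawn per (plate, target) and apply
    to sample wells only, so measured STL carries a plate random effect the
    plate's own standard curve cannot remove. Standard wells: 7-point 1:2
    dilution (20 → 0.3125 ng) per target with Ct = intercept −
    log(mass)/log(E) + noise.
    """
    rng = np.random.default_rng(seed)
    n = len(latent_log_tl)
    n_plates = config.resolved_n_plates
    plates = np.arange(n) % n_plates + 1
    offsets = rng.normal(0.0, config.plate_sd, size=(n_plates, 2))

    eff = {"TEL": config.efficiency_tel, "ALB": config.efficiency_alb}
    icept = {"TEL": config.tel_intercept_ct, "ALB": config.alb_intercept_ct}
    latent = latent_log_tl.to_numpy(float)

    frames = []
    for t_idx, target in enumerate(("TEL", "ALB")):
        ln_e = math.log(eff[target])
        base = icept[target] - math.log(SAMPLE_INPUT_NG) / ln_e
        if target == "TEL":
            base = base - latent / ln_e
        ct0 = base + offsets[plates - 1, t_idx]
        for rep in (1, 2, 3):
            frames.append(pd.DataFrame({
                "sample_id": latent_log_tl.index,
                "plate": plates,
                "target": target,
                "replicate": rep,
                "ct": ct0 + rng.normal(0.0, config.ct_sd, size=n),
                "mass_ng": np.nan,
            }))
        for mass in STANDARD_DILUTION_NG:
            frames.append(pd.DataFrame({
                "sample_id": "STD",
                "plate": np.arange(1, n_plates + 1),
                "target": target,
                "replicate": 1,
                "ct": (icept[target] - math.log(mass) / ln_e
                       + rng.normal(0.0, config.ct_sd, size=n_plates)),
                "mass_ng": mass,
            }))
    ct = pd.concat(frames, ignore_index=True)
    ct["well"] = np.arange(len(ct))
    return ct.sort_values(
        ["plate", "sample_id", "target", "replicate"], kind="stable"
    ).reset_index(drop=True)


def simulate_sperm(
    ages: np.ndarray,
    smoker: np.ndarray,
    latent_log_tl: pd.Series,
    config: CohortConfig,
    seed: int,
) -> pd.DataFrame:
    """Semen parameters: linear age trend + optional telomere effect + noise.

    Each parameter is intercept + age_beta × age + beta_sperm_per_logTL ×
    latent + N(0, sd), clipped to its valid range (percentages to [0, 100],
    counts/concentrations to ≥ 0). Intercepts are set so the cohort mean at
    the reference age equals the configured parameter mean.
    """
    rng = np.random.default_rng(seed)
    latent = latent_log_tl.to_numpy(float)
    out = {"subject_id": latent_log_tl.index}
    for param in SPERM_PARAMETERS:
        mean = config.sperm_means[param]
        beta_age = config.age_betas.get(param, 0.0)
        sd = config.sperm_sds[param]
        intercept = mean - beta_age * config.age_mean
        vals = (intercept + beta_age * ages
                + config.beta_sperm_per_logTL * latent
                + rng.normal(0.0, sd, size=len(ages)))
        if param in _PERCENT_PARAMS:
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.clip(vals, 0.0, None)
        out[param] = vals
    return pd.DataFrame(out).set_index("subject_id").reset_index()


def simulate_cohort(
    config: CohortConfig, panel: list[SnpDefinition] | None = None
) -> Cohort:
    """Compose all stages into one cohort; deterministic given config.seed."""
    panel = list(panel) if panel is not None else default_panel()
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    s_demo, s_geno, s_tl, s_ct, s_sperm = (int(s.generate_state(1)[0] % 2**31)
                                           for s in seeds)

    rng = np.random.default_rng(s_demo)
    ids = _subject_ids(config.n_subjects)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, config.n_subjects),
                   *config.age_range)
    smoker = (rng.random(config.n_subjects) < config.smoking_prevalence)
    subjects = pd.DataFrame({"subject_id": ids, "age": ages,
                             "smoker": smoker.astype(int)})

    genotypes = simulate_genotypes(
        panel, config.n_subjects, config.missing_rate, s_geno,
        bad_subject_rate=config.bad_subject_rate,
        bad_missing_rate=config.bad_missing_rate)
    latent = simulate_latent_tl(
        genotypes, panel, config.beta_tl_per_effect_allele,
        config.sigma_tl, s_tl, intercept=config.tl_intercept)
    ct = simulate_ct_plates(latent, config, s_ct)
    sperm = simulate_sperm(ages, smoker, latent, config, s_sperm)
    return Cohort(subjects=subjects, genotypes=genotypes, latent_log_tl=latent,
                  ct=ct, sperm=sperm, config=config, panel=panel)


# ---------------------------------------------------------------------------
# on-disk format

def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write genotypes.csv, ct.csv and phenotypes.csv (UTF-8, comma, header)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    geno = cohort.genotypes.reset_index()
    paths["genotypes"] = outdir / "genotypes.csv"
    geno.to_csv(paths["genotypes"], index=False, na_rep="")

    ct = cohort.ct[["sample_id", "plate", "well", "target",
                    "replicate", "ct", "mass_ng"]].copy()
    paths["ct"] = outdir / "ct.csv"
    ct.to_csv(paths["ct"], index=False, float_format="%.6f")

    pheno = cohort.subjects.merge(cohort.sperm, on="subject_id")
    paths["phenotypes"] = outdir / "phenotypes.csv"
    pheno.to_csv(paths["phenotypes"], index=False, float_format="%.6f")
    return paths


def read_cohort_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the three delimited tables back as DataFrames."""
    indir = Path(indir)
    genotypes = pd.read_csv(indir / "genotypes.csv", dtype=str)
    genotypes = genotypes.set_index("subject_id")
    ct = pd.read_csv(indir / "ct.csv")
    phenotypes = pd.read_csv(indir / "phenotypes.csv")
    return {"genotypes": genotypes, "ct": ct, "phenotypes": phenotypes}
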