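"""Genotype quality control and model encodings.

Subject call-rate filtering (< 80% discards), Hardy–Weinberg testing,
duplicate-sample concordance, and the additive / codominant encodings used
by the association scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SnpDefinition


class GenotypeDataError(ValueError):
    """Raised when a call is inconsistent with its SNP definition."""


def normalize_call(call) -> tuple[str, str] | None:
    """Parse an ``X/Y`` call into an unordered (sorted) allele pair.

    ``"C/A"`` and ``"A/C"`` are the same genotype. Returns None for
    missing (None/NaN/empty string).
    """
    if call is None or (isinstance(call, float) and math.isnan(call)):
        return None
    s = str(call).strip()
    if not s:
        return None
    parts = s.split("/")
    if len(parts) != 2 or not all(parts):
        raise GenotypeDataError(f"malformed genotype call {call!r}")
    a, b = sorted(p.strip().upper() for p in parts)
    return (a, b)


def subject_call_rates(genotypes: pd.DataFrame) -> pd.Series:
    """Fraction of non-missing calls per subject."""
    if genotypes.empty:
        raise ValueError("empty genotype matrix")
    present = genotypes.notna() & (genotypes.astype(str) != "")
    return present.sum(axis=1) / genotypes.shape[1]


def snp_call_rates(genotypes: pd.DataFrame) -> pd.Series:
    present = genotypes.notna() & (genotypes.astype(str) != "")
    return present.sum(axis=0) / genotypes.shape[0]


def subject_call_rate_filter(
    genotypes: pd.DataFrame, threshold: float = 0.80
) -> tuple[pd.DataFrame, list]:
    """Keep subjects with call rate ≥ threshold; strictly-below discards.

    With an 11-SNP panel, 9/11 genotyped (81.8%) survives an 80% threshold
    and 8/11 (72.7%) does not.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    rates = subject_call_rates(genotypes)
    keep = rates >= threshold
    discarded = list(rates.index[~keep])
    return genotypes.loc[keep], discarded


def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy–Weinberg proportions.

    Expected counts come from the observed allele frequency; p is the
    upper tail of chi-square(1). A monomorphic SNP has no HWE expectation
    and returns (nan, nan).
    """
    counts = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotype counts")
    p_major = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p_major
    if p_major in (0.0, 1.0):
        return (float("nan"), float("nan"))
    expected = n * np.array([p_major ** 2, 2 * p_major * q, q ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE test (two-sided, by heterozygote-count probability).

    Preferable to the chi-square when the minor allele is rare. Enumerates
    all heterozygote counts compatible with the observed allele counts and
    sums the probabilities of outcomes no more likely than the observed one.
    """
    n = n_hom_major + n_het + n_hom_minor
    if n <= 0:
        raise ValueError("no genotype counts")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return float("nan")
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log P(het = h | allele counts) up to a constant, via log-gammas
    def logprob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (h * math.log(2) - math.lgamma(hom_maj + 1)
                - math.lgamma(h + 1) - math.lgamma(hom_min + 1))
    lps = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def genotype_counts(
    calls: pd.Series, snp: SnpDefinition
) -> tuple[int, int, int]:
    """(major-hom, het, minor-hom) counts for one SNP column."""
    counts = [0, 0, 0]
    for subject, call in calls.items():
        pair = normalize_call(call)
        if pair is None:
            continue
        n_minor = sum(1 for a in pair if a == snp.minor_allele)
        if any(a not in snp.alleles for a in pair):
            raise GenotypeDataError(
                f"subject {subject!r}, SNP {snp.snp_id}: allele(s) {pair} "
                f"not in definition {snp.alleles}")
        counts[n_minor] += 1
    return tuple(counts)


def duplicate_concordance(pairs) -> float:
    """Fraction of concordant calls over duplicate-sample pairs.

    ``pairs`` iterates over (calls_a, calls_b) sequences of genotype
    strings for the same subject genotyped twice; only positions where
    both calls are non-missing are compared. Returns nan when nothing is
    comparable.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no duplicate pairs")
    compared = concordant = 0
    for calls_a, calls_b in pairs:
        for a, b in zip(calls_a, calls_b, strict=True):
            pa, pb = normalize_call(a), normalize_call(b)
            if pa is None or pb is None:
                continue
            compared += 1
            concordant += (pa == pb)
    return concordant / compared if compared else float("nan")


def encode_additive(
    genotypes: pd.DataFrame, panel: list[SnpDefinition]
) -> pd.DataFrame:
    """Effect-allele dosage matrix: 0/1/2, NaN preserved for missing."""
    out = {}
    for snp in panel:
        calls = genotypes[snp.snp_id]
        col = np.full(len(calls), np.nan)
        for i, (subject, call) in enumerate(calls.items()):
            pair = normalize_call(call)
            if pair is None:
                continue
            if any(a not in snp.alleles for a in pair):
                raise GenotypeDataError(
                    f"subject {subject!r}, SNP {snp.snp_id}: allele(s) "
                    f"{pair} not in definition {snp.alleles}")
            col[i] = sum(1 for a in pair if a == snp.effect_allele)
        out[snp.snp_id] = col
    return pd.DataFrame(out, index=genotypes.index)


def codominant_contrasts(
    genotypes: pd.DataFrame, panel: list[SnpDefinition]
) -> dict[str, pd.DataFrame]:
    """Per-SNP genotype-class indicators against the major-homozygote.

    For each SNP, up to two indicator columns: heterozygote vs major-hom
    and minor-hom vs major-hom, labelled e.g. ``"T/A vs. T/T"``. A class
    absent from the sample is collapsed (its contrast dropped). Missing
    genotypes are NaN in every indicator.
    """
    out = {}
    for snp in panel:
        calls = genotypes[snp.snp_id]
        n_minor = np.full(len(calls), np.nan)
        for i, (subject, call) in enumerate(calls.items()):
            pair = normalize_call(call)
            if pair is None:
                continue
            if any(a not in snp.alleles for a in pair):
                raise GenotypeDataError(
                    f"subject {subject!r}, SNP {snp.snp_id}: allele(s) "
                    f"{pair} not in definition {snp.alleles}")
            n_minor[i] = sum(1 for a in pair if a == snp.minor_allele)
        ref = f"{snp.major_allele}/{snp.major_allele}"
        labels = {1: f"{snp.major_allele}/{snp.minor_allele} vs. {ref}",
                  2: f"{snp.minor_allele}/{snp.minor_allele} vs. {ref}"}
        cols = {}
        for cls in (1, 2):
            if np.any(n_minor == cls):
                ind = np.where(np.isnan(n_minor), np.nan,
                               (n_minor == cls).astype(float))
                cols[labels[cls]] = ind
        out[snp.snp_id] = pd.DataFrame(cols, index=genotypes.index)
    return out


@dataclass
class QcReport:
    """Structured genotype-QC summary."""

    n_subjects: int
    n_kept: int
    call_rate_threshold: float
    subject_call_rates: dict = field(repr=False)
    snp_call_rates: dict = field(repr=False)
    discarded_subjects: list = field(default_factory=list)
    hwe_results: dict = field(default_factory=dict)  # snp_id -> {chi2, p}
    duplicate_concordance: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_kept": self.n_kept,
            "call_rate_threshold": self.call_rate_threshold,
            "discarded_subjects": list(self.discarded_subjects),
            "mean_snp_call_rate": float(np.mean(list(self.snp_call_rates.values()))),
            "snp_call_rates": self.snp_call_rates,
            "hwe_results": self.hwe_results,
            "duplicate_concordance": self.duplicate_concordance,
        }


def run_qc(
    genotypes: pd.DataFrame,
    panel: list[SnpDefinition],
    call_rate_threshold: float = 0.80,
    duplicate_pairs=None,
) -> tuple[pd.DataFrame, pd.DataFrame, QcReport]:
    """Full QC: filter subjects, test HWE per SNP, encode dosages.

    Returns (kept genotypes, dosage matrix, report). SNP-level call rates
    are reported but no SNP is auto-dropped.
    """
    rates = subject_call_rates(genotypes)
    kept, discarded = subject_call_rate_filter(genotypes, call_rate_threshold)
    hwe = {}
    for snp in panel:
        counts = genotype_counts(kept[snp.snp_id], snp)
        if sum(counts) == 0:
            hwe[snp.snp_id] = {"chi2": float("nan"), "p": float("nan")}
            continue
        chi2, p = hwe_test(*counts)
        hwe[snp.snp_id] = {"chi2": chi2, "p": p,
                           "counts": list(counts)}
    dosages = encode_additive(kept, panel)
    report = QcReport(
        n_subjects=len(genotypes), n_kept=len(kept),
        call_rate_threshold=call_rate_threshold,
        subject_call_rates=rates.to_dict(),
        snp_call_rates=snp_call_rates(genotypes).to_dict(),
        discarded_subjects=discarded,
        hwe_results=hwe,
        duplicate_concordance=(duplicate_concordance(duplicate_pairs)
                               if duplicate_pairs else None),
    )
    return kept, dosages, report
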