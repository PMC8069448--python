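"""Telomere genetic scores (teloscores) and quintile categorization.

The unweighted score sums effect-allele dosages over the panel (0–22 for
11 SNPs); the weighted score multiplies each dosage by its literature
per-allele effect. Scaled variants divide by the number of genotyped SNPs
and multiply by the panel size, making subjects with partial genotyping
comparable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SnpDefinition


def unweighted_score(dosages) -> float:
    """Sum of non-missing effect-allele dosages; NaN if all missing."""
    d = np.asarray(dosages, dtype=float)
    if np.all(np.isnan(d)):
        return float("nan")
    return float(np.nansum(d))


def weighted_score(dosages, weights) -> float:
    """Sum of dosage × weight over non-missing SNPs; NaN if all missing."""
    d = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise ValueError("dosages and weights must align")
    if np.any(np.isnan(w)):
        raise ValueError("missing weight in panel configuration")
    if np.all(np.isnan(d)):
        return float("nan")
    return float(np.nansum(d * w))


def scaled_score(raw: float, n_genotyped: int, panel_size: int = 11) -> float:
    """raw / n_genotyped × panel_size; undefined for n_genotyped = 0."""
    if n_genotyped < 1 or n_genotyped > panel_size:
        raise ValueError(
            f"n_genotyped={n_genotyped} outside 1..{panel_size}")
    return raw / n_genotyped * panel_size


def compute_scores(
    dosages: pd.DataFrame,
    panel: list[SnpDefinition],
    with_quintiles: bool = True,
) -> pd.DataFrame:
    """Per-subject score table from a dosage matrix.

    Columns: n_genotyped, unweighted_raw, weighted_raw, unweighted_scaled,
    weighted_scaled (+ a quintile column per scaled score). Subjects with
    no genotyped SNPs get NaN scores and fall out of downstream models.
    """
    ids = [s.snp_id for s in panel]
    d = dosages[ids].to_numpy(float)
    w = np.array([s.weight for s in panel])
    n_geno = np.sum(~np.isnan(d), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        unw = np.nansum(d, axis=1)
        wgt = np.nansum(d * w, axis=1)
    unw = np.where(n_geno == 0, np.nan, unw)
    wgt = np.where(n_geno == 0, np.nan, wgt)
    with np.errstate(divide="ignore", invalid="ignore"):
        unw_scaled = np.where(n_geno > 0, unw / n_geno * len(panel), np.nan)
        wgt_scaled = np.where(n_geno > 0, wgt / n_geno * len(panel), np.nan)
    out = pd.DataFrame({
        "n_genotyped": n_geno,
        "unweighted_raw": unw,
        "weighted_raw": wgt,
        "unweighted_scaled": unw_scaled,
        "weighted_scaled": wgt_scaled,
    }, index=dosages.index)
    if with_quintiles:
        out["unweighted_quintile"] = quintile_categorize(out["unweighted_scaled"])
        out["weighted_quintile"] = quintile_categorize(out["weighted_scaled"])
    return out


def quintile_categorize(values) -> pd.Series:
    """Rank-based quintiles 1–5; 1 = lowest fifth (reference group).

    Category = 1 + floor((rank − 1) × 5 / n) with minimum ranks, so tied
    values share the lower category and counts differ by at most one in
    the absence of ties. NaN values stay NaN. A degenerate input (< 5
    distinct values) is categorized all the same but warned about.
    """
    s = pd.Series(values).astype(float)
    if s.notna().sum() == 0:
        raise ValueError("no values to categorize")
    v = s.dropna()
    if v.nunique() < 5:
        warnings.warn(
            f"fewer than 5 distinct values ({v.nunique()}); quintile "
            "categories are degenerate", UserWarning, stacklevel=2)
    ranks = stats.rankdata(v.to_numpy(), method="min")
    cats = 1 + ((ranks - 1) * 5) // len(v)
    out = pd.Series(np.nan, index=s.index, dtype=float)
    out.loc[v.index] = cats
    return out
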