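"""Association scan: telomere measures against semen parameters.

Linear models adjusted for age and smoking, with the plate handled as a
random intercept when log STL is the outcome and by prior residualization
when STL is the exposure. Exposures are the residualized log STL (linear
and quintile forms), the scaled teloscores (linear and quintile forms),
and each panel SNP (additive and codominant codings). Wald 95% CIs
throughout; multiple testing on the SNP scan at the Bonferroni threshold
alpha / (11 SNPs × 3 inheritance coefficients) = 0.05/33.

The random-intercept model is fitted by profiled REML: for a single
grouping factor the covariance is block-diagonal, so all GLS
cross-products reduce to group-sum corrections and the restricted
likelihood is maximized over the single variance ratio
λ = σ²_plate / σ²_resid with a scalar optimizer. With λ = 0 the fit is
ordinary least squares exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genoqc import codominant_contrasts
from .scores import quintile_categorize


class ModelError(ValueError):
    """Degenerate design: constant or collinear term."""


class InsufficientDataError(ValueError):
    """Too few complete cases to fit."""


MIN_COMPLETE_CASES = 10
DEFAULT_COVARIATES = ("age", "smoker")


@dataclass
class AssociationRecord:
    """One fitted contrast of the scan."""

    outcome: str
    exposure: str
    form: str            # linear | quintile | additive | codominant
    term: str            # coefficient label (e.g. "Q4 vs. Q1", "T/A vs. T/T")
    family: str          # "snp" | "score" | "stl" (multiple-testing family)
    n: int
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    plate_handling: str = "none"
    significant: bool | None = None
    threshold: float | None = None


# ---------------------------------------------------------------------------
# estimation core

@dataclass
class _FitResult:
    beta: np.ndarray
    se: np.ndarray
    ci: np.ndarray        # (p, 2)
    p_values: np.ndarray
    n: int
    sigma2: float
    lam: float = 0.0      # variance ratio sigma2_group / sigma2_resid


def _check_design(X: np.ndarray, names: list[str]) -> None:
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            raise ModelError(f"constant term {names[j]!r}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError(f"collinear design involving {names[1:]}")


def wald_ols(y: np.ndarray, X: np.ndarray, names: list[str]) -> _FitResult:
    """OLS with classical (homoskedastic) Wald t statistics and 95% CIs."""
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} <= p={p}")
    _check_design(X, names)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    ci = np.column_stack([beta - tcrit * se, beta + tcrit * se])
    return _FitResult(beta=beta, se=se, ci=ci, p_values=pvals, n=n,
                      sigma2=sigma2)


def random_intercept_reml(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, names: list[str]
) -> _FitResult:
    """Linear mixed model with one random intercept, by profiled REML.

    Exact for the single-grouping-factor case: V = σ²(I + λ Z Z') is block
    diagonal, V⁻¹ corrections are rank-one per group, and the restricted
    likelihood is profiled down to the scalar ratio λ ≥ 0. Fixed-effect
    inference is Wald with normal critical values (the convention for
    mixed-model fixed effects). λ = 0 reproduces the OLS estimates.
    """
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} <= p={p}")
    _check_design(X, names)
    _, gidx = np.unique(groups, return_inverse=True)
    q = gidx.max() + 1
    nj = np.bincount(gidx, minlength=q).astype(float)
    SX = np.zeros((q, p))
    np.add.at(SX, gidx, X)
    Sy = np.bincount(gidx, weights=y, minlength=q)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    df = n - p

    def profile(lam: float):
        w = lam / (1.0 + lam * nj)
        A = XtX - (SX * w[:, None]).T @ SX
        b = Xty - SX.T @ (w * Sy)
        yy = yty - float(w @ (Sy ** 2))
        beta = np.linalg.solve(A, b)
        rss = yy - float(beta @ b)
        return A, beta, rss

    def neg2_reml(lam: float) -> float:
        A, _, rss = profile(lam)
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0 or rss <= 0:
            return np.inf
        return (float(np.sum(np.log1p(lam * nj))) + logdet_a
                + df * np.log(rss / df))

    res = optimize.minimize_scalar(
        lambda u: neg2_reml(np.exp(u)), bounds=(-12.0, 10.0),
        method="bounded", options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    if neg2_reml(0.0) <= res.fun:
        lam = 0.0
    A, beta, rss = profile(lam)
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    ci = np.column_stack([beta - zcrit * se, beta + zcrit * se])
    return _FitResult(beta=beta, se=se, ci=ci, p_values=pvals, n=n,
                      sigma2=sigma2, lam=lam)


# ---------------------------------------------------------------------------
# model-level interface

def _assemble(columns: dict, outcome: str, exposure_cols: list[str],
              covariates, extra: list[str] = ()):
    cols = [outcome, *exposure_cols, *covariates, *extra]
    mat = np.column_stack([np.asarray(columns[c], dtype=float) for c in cols])
    mask = np.all(np.isfinite(mat), axis=1)
    mat = mat[mask]
    if mat.shape[0] < MIN_COMPLETE_CASES:
        raise InsufficientDataError(
            f"{outcome} ~ {exposure_cols}: {mat.shape[0]} complete cases")
    y = mat[:, 0]
    k = len(exposure_cols)
    X = np.column_stack([np.ones(len(y)), mat[:, 1:1 + k + len(covariates)]])
    extra_vals = mat[:, 1 + k + len(covariates):]
    return y, X, extra_vals, mask


def fit_linear(
    data: "pd.DataFrame | dict",
    outcome: str,
    exposure_cols: list[str],
    exposure: str,
    form: str,
    family: str,
    covariates=DEFAULT_COVARIATES,
    term_labels: list[str] | None = None,
) -> list[AssociationRecord]:
    """OLS of ``outcome`` on exposure column(s) plus covariates.

    Emits one record per exposure column (quintile exposures pass four
    indicator columns and get four records; codominant SNPs up to two).
    """
    columns = data if isinstance(data, dict) else {c: data[c].to_numpy()
                                                   for c in data.columns}
    y, X, _, _ = _assemble(columns, outcome, exposure_cols, covariates)
    names = ["(intercept)", *(term_labels or exposure_cols), *covariates]
    fit = wald_ols(y, X, names)
    return _records(fit, outcome, exposure, form, family,
                    term_labels or exposure_cols, "none")


def fit_plate_mixed(
    data: "pd.DataFrame | dict",
    outcome: str,
    exposure_cols: list[str],
    exposure: str,
    form: str,
    family: str,
    plate_col: str = "plate",
    covariates=DEFAULT_COVARIATES,
    term_labels: list[str] | None = None,
) -> list[AssociationRecord]:
    """Mixed model with a plate random intercept (log STL outcomes).

    Falls back to OLS with a warning when only one plate is present.
    """
    columns = data if isinstance(data, dict) else {c: data[c].to_numpy()
                                                   for c in data.columns}
    y, X, extra, _ = _assemble(columns, outcome, exposure_cols, covariates,
                               extra=[plate_col])
    plates = extra[:, 0]
    names = ["(intercept)", *(term_labels or exposure_cols), *covariates]
    if np.unique(plates).size < 2:
        warnings.warn("single plate: falling back to OLS", UserWarning,
                      stacklevel=2)
        fit = wald_ols(y, X, names)
        handling = "ols_fallback"
    else:
        fit = random_intercept_reml(y, X, plates, names)
        handling = "random_effect"
    return _records(fit, outcome, exposure, form, family,
                    term_labels or exposure_cols, handling)


def _records(fit: _FitResult, outcome, exposure, form, family,
             term_labels, plate_handling) -> list[AssociationRecord]:
    recs = []
    for j, label in enumerate(term_labels, start=1):
        recs.append(AssociationRecord(
            outcome=outcome, exposure=exposure, form=form, term=str(label),
            family=family, n=fit.n,
            coefficient=float(fit.beta[j]),
            ci_low=float(fit.ci[j, 0]), ci_high=float(fit.ci[j, 1]),
            p_value=float(fit.p_values[j]),
            plate_handling=plate_handling))
    return recs


def apply_multiple_testing(
    records: list[AssociationRecord], alpha: float = 0.05, m: int = 33
) -> list[AssociationRecord]:
    """Flag records at the Bonferroni threshold alpha/m (in place)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    for r in records:
        r.significant = bool(r.p_value < threshold)
        r.threshold = threshold
    return records


# ---------------------------------------------------------------------------
# the full scan

#: Raw semen-parameter outcomes of the scan.
SPERM_OUTCOMES = (
    "concentration", "total_number", "progressive_motility",
    "nonprogressive_motility", "total_motility", "normal_morphology",
    "normal_acrosome", "normal_head", "normal_flagellum",
)


_QUINTILE_LABELS = {2: "2nd vs. 1st quintile", 3: "3rd vs. 1st quintile",
                    4: "4th vs. 1st quintile", 5: "5th vs. 1st quintile"}


def _quintile_indicators(values: np.ndarray) -> dict[str, np.ndarray]:
    """Indicator columns for quintiles 2..5 vs the first (reference)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        cats = quintile_categorize(pd.Series(values)).to_numpy()
    cols = {}
    for k, label in _QUINTILE_LABELS.items():
        if np.any(cats == k):
            cols[label] = np.where(np.isnan(cats), np.nan,
                                   (cats == k).astype(float))
    return cols


def run_scan(
    pheno: pd.DataFrame,
    stl: pd.DataFrame,
    score_table: pd.DataFrame,
    dosages: pd.DataFrame,
    genotypes: pd.DataFrame,
    abcd_table: pd.DataFrame,
    panel: list,
    alpha: float = 0.05,
    m: int = 33,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the complete exposure × outcome × model enumeration.

    Exposures: residualized log STL (linear + quintiles), scaled
    unweighted/weighted teloscores (linear + quintiles), and each panel
    SNP (additive + codominant). Outcomes: the nine semen parameters plus
    the ABCD and ABCD_mot composites; SNPs and scores are additionally
    tested against log STL with the plate as a random intercept. All
    models adjust for age and smoking; missing data are handled
    complete-case per model.

    Returns the records as a DataFrame plus a list of logged skips
    (models that could not be fitted, with reasons); nothing is dropped
    silently. SNP-family records are flagged at alpha/m, the rest at
    nominal alpha.
    """
    df = pheno.merge(stl[["subject_id", "plate", "log_stl",
                          "log_stl_residual"]], on="subject_id", how="left")
    df = df.merge(abcd_table[["subject_id", "abcd_total", "abcd_mot"]],
                  on="subject_id", how="left")
    df = df.merge(score_table[["unweighted_scaled", "weighted_scaled"]],
                  left_on="subject_id", right_index=True, how="left")
    df = df.merge(dosages, left_on="subject_id", right_index=True, how="left",
                  suffixes=(None, "_dosage"))

    columns: dict[str, np.ndarray] = {
        c: df[c].to_numpy(float) if c != "subject_id" else df[c].to_numpy()
        for c in df.columns
    }
    sperm_outcomes = [*SPERM_OUTCOMES, "abcd_total", "abcd_mot"]
    snp_records: list[AssociationRecord] = []
    other_records: list[AssociationRecord] = []
    skips: list[dict] = []

    def attempt(bucket, fitter, **kw):
        try:
            bucket.extend(fitter(columns, **kw))
        except (ModelError, InsufficientDataError) as exc:
            skips.append({"outcome": kw["outcome"], "exposure": kw["exposure"],
                          "form": kw["form"], "reason": str(exc)})

    # --- STL (exposure) vs sperm parameters: residualized log STL
    stl_quint = _quintile_indicators(columns["log_stl_residual"])
    columns.update({f"stl::{k}": v for k, v in stl_quint.items()})
    for outcome in sperm_outcomes:
        attempt(other_records, fit_linear, outcome=outcome,
                exposure_cols=["log_stl_residual"],
                exposure="log_stl_residual", form="linear", family="stl")
        attempt(other_records, fit_linear, outcome=outcome,
                exposure_cols=[f"stl::{k}" for k in stl_quint],
                term_labels=list(stl_quint),
                exposure="log_stl_residual", form="quintile", family="stl")

    # --- teloscores vs sperm parameters and vs log STL
    for score_col in ("unweighted_scaled", "weighted_scaled"):
        quint = _quintile_indicators(columns[score_col])
        columns.update({f"{score_col}::{k}": v for k, v in quint.items()})
        qcols = [f"{score_col}::{k}" for k in quint]
        for outcome in sperm_outcomes:
            attempt(other_records, fit_linear, outcome=outcome,
                    exposure_cols=[score_col], exposure=score_col,
                    form="linear", family="score")
            attempt(other_records, fit_linear, outcome=outcome,
                    exposure_cols=qcols, term_labels=list(quint),
                    exposure=score_col, form="quintile", family="score")
        attempt(other_records, fit_plate_mixed, outcome="log_stl",
                exposure_cols=[score_col], exposure=score_col,
                form="linear", family="score")
        attempt(other_records, fit_plate_mixed, outcome="log_stl",
                exposure_cols=qcols, term_labels=list(quint),
                exposure=score_col, form="quintile", family="score")

    # --- single SNPs: additive and codominant
    codominant = codominant_contrasts(genotypes, panel)
    subject_order = df["subject_id"]
    for snp in panel:
        rsid = snp.snp_id
        contrasts = codominant[rsid].reindex(subject_order)
        ccols = []
        for label in contrasts.columns:
            key = f"{rsid}::{label}"
            columns[key] = contrasts[label].to_numpy(float)
            ccols.append((key, label))
        for outcome in sperm_outcomes:
            attempt(snp_records, fit_linear, outcome=outcome,
                    exposure_cols=[rsid], term_labels=["additive"],
                    exposure=rsid, form="additive", family="snp")
            if ccols:
                attempt(snp_records, fit_linear, outcome=outcome,
                        exposure_cols=[k for k, _ in ccols],
                        term_labels=[l for _, l in ccols],
                        exposure=rsid, form="codominant", family="snp")
        attempt(snp_records, fit_plate_mixed, outcome="log_stl",
                exposure_cols=[rsid], term_labels=["additive"],
                exposure=rsid, form="additive", family="snp")
        if ccols:
            attempt(snp_records, fit_plate_mixed, outcome="log_stl",
                    exposure_cols=[k for k, _ in ccols],
                    term_labels=[l for _, l in ccols],
                    exposure=rsid, form="codominant", family="snp")

    apply_multiple_testing(snp_records, alpha=alpha, m=m)
    apply_multiple_testing(other_records, alpha=alpha, m=1)
    records = snp_records + other_records
    return pd.DataFrame([asdict(r) for r in records]), skips


def render_report(results: pd.DataFrame) -> str:
    """Plain-text report: one block per outcome, rows per exposure term."""
    lines = []
    for outcome, sub in results.groupby("outcome", sort=True):
        lines.append(f"== {outcome} ==")
        view = sub[["exposure", "form", "term", "n", "coefficient",
                    "ci_low", "ci_high", "p_value", "significant"]].copy()
        view["coef (95% CI)"] = [
            f"{c:.3f} ({lo:.3f} to {hi:.3f})"
            for c, lo, hi in zip(view["coefficient"], view["ci_low"],
                                 view["ci_high"])]
        lines.append(view[["exposure", "form", "term", "n", "coef (95% CI)",
                           "p_value", "significant"]].to_string(index=False))
        lines.append("")
    return "\n".join(lines)
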