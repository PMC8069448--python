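"""Relative telomere quantification from qPCR cycle thresholds.

Implements the full raw-Ct → relative sperm telomere length (STL) path:

* per-plate standard curves (Ct vs log10 input mass) and amplification
  efficiency ``E = 10**(-1/slope)``;
* triplicate quality control (the verbatim "5% of the SD" discard rule,
  plus a practical CV-based alternative);
* the Pfaffl efficiency-corrected ratio
  ``E_tel**dCt_tel / E_alb**dCt_alb`` against a 5 ng calibrator read off
  the standard curve;
* plate residualization of log STL;
* the 3'-overlap primer-dimer product model used to predict the telomere
  amplicon length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Telomere primer pair (5'→3'), as used for the Tel amplification.
TELG_PRIMER = "ACACTAAGGTTTGGGTTTGGGTTTGGGTTTGGGTTAGTGT"
TELC_PRIMER = "TGTTAGGTATCCCTATCCCTATCCCTATCCCTATCCCTAACA"

#: Calibrator input mass (ng): sample ΔCts are taken against the
#: standard-curve Ct predicted at this mass.
CALIBRATOR_MASS_NG = 5.0

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class StandardCurveError(ValueError):
    """Raised when a standard curve cannot be fitted."""


class TriplicateQcError(ValueError):
    """Raised on an empty or invalid replicate set."""


class QuantificationError(ValueError):
    """Raised when a sample cannot be quantified (e.g. missing curve)."""


class PrimerProductError(ValueError):
    """Raised when the primer pair predicts no product."""


# ---------------------------------------------------------------------------
# standard curves

@dataclass(frozen=True)
class StandardCurveFit:
    """Least-squares fit of Ct on log10(input mass in ng).

    ``efficiency`` is the per-cycle amplification factor 10**(-1/slope);
    perfect doubling gives slope ≈ −3.3219 and efficiency 2.0.
    """

    plate: object
    target: str
    slope: float          # cycles per log10(ng); negative
    intercept: float      # Ct at 1 ng
    efficiency: float
    r_squared: float
    n_points: int

    def predict_ct(self, mass_ng: float) -> float:
        return self.intercept + self.slope * math.log10(mass_ng)

    @property
    def calibrator_ct(self) -> float:
        return self.predict_ct(CALIBRATOR_MASS_NG)


def fit_standard_curve(
    dilution_points: "list[tuple[float, float]] | np.ndarray",
    plate: object = None,
    target: str = "",
) -> StandardCurveFit:
    """Fit a standard curve from ``(mass_ng, ct)`` dilution points.

    Requires at least three distinct positive masses. Sanity of the result
    (negative slope, efficiency in (1, 4)) is the caller's concern; the fit
    itself only rejects degenerate inputs.
    """
    pts = np.asarray(dilution_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise StandardCurveError(
            f"standard curve for plate={plate!r} target={target!r}: "
            "need >= 3 (mass, ct) points"
        )
    mass, ct = pts[:, 0], pts[:, 1]
    if np.any(mass <= 0):
        raise StandardCurveError("non-positive input mass in standard curve")
    x = np.log10(mass)
    if np.unique(x).size < 3:
        raise StandardCurveError("fewer than 3 distinct masses in standard curve")
    slope, intercept = np.polyfit(x, ct, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((ct - fitted) ** 2))
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope == 0:
        raise StandardCurveError("flat standard curve (zero slope)")
    eff = 10.0 ** (-1.0 / slope)
    return StandardCurveFit(
        plate=plate, target=target, slope=float(slope),
        intercept=float(intercept), efficiency=float(eff),
        r_squared=r2, n_points=int(pts.shape[0]),
    )


# ---------------------------------------------------------------------------
# triplicate QC

@dataclass
class TriplicateQc:
    """Outcome of replicate-set QC: survivors, their mean, per-well flags."""

    kept: np.ndarray
    mean_ct: float
    discarded: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    usable: bool = True
    rule: str = "literal_5pct_sd"


def _sd(values: np.ndarray) -> float:
    # sample SD, n-1 denominator (configurable would be ddof=0)
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def qc_triplicates(
    cts,
    rule: str = "literal_5pct_sd",
    threshold: float = 0.05,
    ddof: int = 1,
) -> TriplicateQc:
    """Apply replicate QC to 1–3 Ct values and average the survivors.

    ``literal_5pct_sd`` discards every value whose deviation from the
    replicate mean exceeds ``threshold`` × SD (default 5% of the SD) in a
    single pass, then averages the survivors. This rule is extremely
    stringent: any replicate set whose values are not all equal loses at
    least two wells, so sets with real noise are almost always flagged
    unusable. It is provided verbatim; the ``cv_threshold`` mode is the
    practical alternative: keep all wells when the coefficient of variation
    SD/|mean| is within ``threshold``, otherwise drop the single most
    deviant well and re-check the remaining pair.

    A set reduced below two survivors is flagged ``usable=False``.
    """
    values = np.asarray(cts, dtype=float).ravel()
    if values.size == 0:
        raise TriplicateQcError("empty replicate set")
    if not np.all(np.isfinite(values)):
        raise TriplicateQcError("non-finite Ct in replicate set")

    if rule == "literal_5pct_sd":
        sd = float(np.std(values, ddof=ddof)) if values.size > ddof else 0.0
        dev = np.abs(values - values.mean())
        keep = dev <= threshold * sd
        kept, dropped = values[keep], values[~keep]
    elif rule == "cv_threshold":
        kept, dropped = values, np.array([], dtype=float)
        mean = kept.mean()
        cv = (_sd(kept) / abs(mean)) if mean != 0 else np.inf
        if kept.size >= 2 and cv > threshold:
            worst = int(np.argmax(np.abs(kept - mean)))
            dropped = kept[[worst]]
            kept = np.delete(kept, worst)
            mean = kept.mean()
            cv = (_sd(kept) / abs(mean)) if mean != 0 else np.inf
            if cv > threshold:
                dropped = np.concatenate([dropped, kept])
                kept = np.array([], dtype=float)
    else:
        raise ValueError(f"unknown triplicate rule {rule!r}")

    usable = kept.size >= 2 or (kept.size == values.size == 1)
    mean_ct = float(kept.mean()) if kept.size else float("nan")
    return TriplicateQc(kept=kept, mean_ct=mean_ct, discarded=dropped,
                        usable=usable, rule=rule)


# ---------------------------------------------------------------------------
# Pfaffl ratio and plate residualization

def pfaffl_ratio(
    mean_ct_tel: float,
    mean_ct_alb: float,
    curve_tel: StandardCurveFit,
    curve_alb: StandardCurveFit,
) -> float:
    """Efficiency-corrected Tel/ALB ratio against the 5 ng calibrator.

    ratio = E_tel**(Ct_cal,tel − Ct_tel) / E_alb**(Ct_cal,alb − Ct_alb),
    with calibrator Cts the fitted standard-curve values at 5 ng. With both
    efficiencies exactly 2 this reduces to the classical 2**ΔΔCt form.
    """
    if curve_tel is None or curve_alb is None:
        raise QuantificationError("missing standard curve for plate")
    for c in (curve_tel, curve_alb):
        if not (1.0 < c.efficiency < 4.0):
            raise QuantificationError(
                f"efficiency {c.efficiency:.3f} for {c.target} on plate "
                f"{c.plate!r} outside sanity band (1, 4)"
            )
    d_tel = curve_tel.calibrator_ct - mean_ct_tel
    d_alb = curve_alb.calibrator_ct - mean_ct_alb
    return float(curve_tel.efficiency ** d_tel / curve_alb.efficiency ** d_alb)


def residualize_on_plate(log_stl: pd.Series, plates: pd.Series) -> pd.Series:
    """Residuals of log STL on plate indicators (= within-plate centering).

    Equivalent to OLS of log STL on plate dummies; residuals sum to zero
    within each plate.
    """
    log_stl = pd.Series(log_stl).astype(float)
    return log_stl - log_stl.groupby(pd.Series(plates).values).transform("mean")


# ---------------------------------------------------------------------------
# primer product model

def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def predict_primer_product_length(primer_a: str, primer_b: str) -> int:
    """Predicted primer-dimer product size from maximal 3'-terminal overlap.

    Finds the largest k such that the 3'-terminal k bases of ``primer_a``
    are perfectly Watson–Crick complementary (antiparallel) to the
    3'-terminal k bases of ``primer_b``; the mutually primed extension then
    yields a product of ``len(a) + len(b) − k`` bp. Internal mismatches and
    partial duplexes are not modelled. Raises if no 3' overlap exists.
    """
    for name, seq in (("primer_a", primer_a), ("primer_b", primer_b)):
        if not seq or set(seq) - set("ACGT"):
            raise ValueError(f"{name}: non-empty A/C/G/T string required")
    best = 0
    for k in range(1, min(len(primer_a), len(primer_b)) + 1):
        if _revcomp(primer_a[-k:]) == primer_b[-k:]:
            best = k
    if best == 0:
        raise PrimerProductError("no 3'-terminal complementary overlap; "
                                 "no predicted product")
    return len(primer_a) + len(primer_b) - best


# ---------------------------------------------------------------------------
# vectorized triplicate QC (regular plate layouts)

def _qc_arrays(cts: np.ndarray, rule: str, threshold: float):
    """Vectorized triplicate QC over an (N, 3) Ct array.

    Same semantics as :func:`qc_triplicates` applied row-wise; returns
    (mean_ct, usable, any_discarded).
    """
    n = cts.shape[0]
    mean3 = cts.mean(axis=1)
    sd3 = cts.std(axis=1, ddof=1)
    dev = np.abs(cts - mean3[:, None])
    if rule == "literal_5pct_sd":
        keep = dev <= threshold * sd3[:, None]
        count = keep.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0,
                            np.sum(np.where(keep, cts, 0.0), axis=1)
                            / np.maximum(count, 1), np.nan)
        usable = count >= 2
        discarded = count < 3
        return np.where(usable, mean, np.nan), usable, discarded
    if rule != "cv_threshold":
        raise ValueError(f"unknown triplicate rule {rule!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv3 = np.where(mean3 != 0, sd3 / np.abs(mean3), np.inf)
    keep_all = cv3 <= threshold
    worst = np.argmax(dev, axis=1)
    mask = np.ones_like(cts, dtype=bool)
    mask[np.arange(n), worst] = False
    pair = cts[mask].reshape(n, 2)
    mean2 = pair.mean(axis=1)
    sd2 = np.abs(pair[:, 0] - pair[:, 1]) / np.sqrt(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean2 != 0, sd2 / np.abs(mean2), np.inf)
    pair_ok = cv2 <= threshold
    mean = np.where(keep_all, mean3, np.where(pair_ok, mean2, np.nan))
    usable = keep_all | pair_ok
    return mean, usable, ~keep_all


def _quantify_regular(samples: pd.DataFrame, curves: dict,
                      rule: str, threshold: float) -> pd.DataFrame | None:
    """Fast path for the regular layout: every subject has exactly three
    TEL and three ALB wells on a single plate. Returns None when the
    layout is irregular (the generic per-subject path then applies)."""
    counts = samples.groupby(["sample_id", "target"], sort=False).size()
    if not (counts == 3).all():
        return None
    wide = samples.pivot_table(index=["sample_id", "plate"],
                               columns=["target", "replicate"], values="ct",
                               aggfunc="first", sort=True)
    try:
        tel = wide["TEL"].to_numpy(float)
        alb = wide["ALB"].to_numpy(float)
    except KeyError:
        return None
    if tel.shape[1] != 3 or alb.shape[1] != 3 or np.isnan(tel).any() \
            or np.isnan(alb).any():
        return None
    subjects = wide.index.get_level_values("sample_id")
    if subjects.duplicated().any():  # subject split across plates
        return None
    plates = wide.index.get_level_values("plate").to_numpy()

    mean_tel, ok_tel, disc_tel = _qc_arrays(tel, rule, threshold)
    mean_alb, ok_alb, disc_alb = _qc_arrays(alb, rule, threshold)
    usable = ok_tel & ok_alb

    cal_tel = np.full(len(plates), np.nan)
    cal_alb = np.full(len(plates), np.nan)
    eff_tel = np.full(len(plates), np.nan)
    eff_alb = np.full(len(plates), np.nan)
    for p in np.unique(plates):
        sel = plates == p
        ct_curve, ab_curve = curves.get((p, "TEL")), curves.get((p, "ALB"))
        if ct_curve is None or ab_curve is None:
            usable[sel] = False
            continue
        for c in (ct_curve, ab_curve):
            if not (1.0 < c.efficiency < 4.0):
                raise QuantificationError(
                    f"efficiency {c.efficiency:.3f} for {c.target} on plate "
                    f"{c.plate!r} outside sanity band (1, 4)")
        cal_tel[sel], cal_alb[sel] = ct_curve.calibrator_ct, ab_curve.calibrator_ct
        eff_tel[sel], eff_alb[sel] = ct_curve.efficiency, ab_curve.efficiency

    with np.errstate(invalid="ignore"):
        ratio = np.where(
            usable,
            eff_tel ** (cal_tel - mean_tel) / eff_alb ** (cal_alb - mean_alb),
            np.nan)
        log_stl = np.where(usable, np.log(ratio), np.nan)
    flags = np.where(~usable, "unusable",
                     np.where(disc_tel | disc_alb, "wells_discarded", "ok"))
    out = pd.DataFrame({
        "subject_id": subjects, "plate": plates,
        "mean_ct_tel": np.where(ok_tel, mean_tel, np.nan),
        "mean_ct_alb": np.where(ok_alb, mean_alb, np.nan),
        "stl_ratio": ratio, "log_stl": log_stl, "qc_flag": flags,
    })
    out["log_stl_residual"] = residualize_on_plate(out["log_stl"], out["plate"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# plate-set quantification pipeline

def fit_all_standard_curves(ct: pd.DataFrame, pooled: bool = False) -> dict:
    """Fit per-(plate, target) standard curves from the standard wells.

    Standard wells are rows with a finite ``mass_ng``. With ``pooled=True``
    one curve per target is fitted from all plates' standard wells and used
    for every plate (sparse-plate fallback).
    """
    std = ct[np.isfinite(ct["mass_ng"].astype(float))]
    if std.empty:
        raise StandardCurveError("no standard-curve wells (finite mass_ng) found")
    curves: dict = {}
    if pooled:
        for target, sub in std.groupby("target"):
            fit = fit_standard_curve(sub[["mass_ng", "ct"]].to_numpy(),
                                     plate="pooled", target=str(target))
            for plate in ct["plate"].unique():
                curves[(plate, target)] = fit
    else:
        for (plate, target), sub in std.groupby(["plate", "target"]):
            curves[(plate, target)] = fit_standard_curve(
                sub[["mass_ng", "ct"]].to_numpy(), plate=plate, target=str(target))
    return curves


def quantify(
    ct: pd.DataFrame,
    rule: str = "cv_threshold",
    threshold: float = 0.05,
    pooled_curves: bool = False,
) -> pd.DataFrame:
    """Raw Ct table → per-subject STL table.

    ``ct`` columns: sample_id, plate, target (TEL|ALB), replicate, ct,
    mass_ng (finite only for standard wells). Returns one row per subject:
    mean Cts after triplicate QC, Pfaffl ``stl_ratio``, natural-log
    ``log_stl``, plate-centered ``log_stl_residual`` and a ``qc_flag``
    ("ok", "wells_discarded", or "unusable"; unusable subjects carry NaN
    quantities).

    The default rule here is the CV alternative, not the verbatim
    5%-of-SD rule: the latter flags essentially every noisy triplicate
    unusable (see :func:`qc_triplicates`) and is opted into explicitly.
    """
    curves = fit_all_standard_curves(ct, pooled=pooled_curves)
    samples = ct[~np.isfinite(ct["mass_ng"].astype(float))]
    fast = _quantify_regular(samples, curves, rule, threshold)
    if fast is not None:
        return fast
    rows = []
    for subject, sub in samples.groupby("sample_id", sort=True):
        plate = sub["plate"].iloc[0]
        means, flags = {}, []
        for target in ("TEL", "ALB"):
            wells = sub.loc[sub["target"] == target, "ct"].to_numpy(float)
            if wells.size == 0:
                means[target] = float("nan")
                flags.append("unusable")
                continue
            qc = qc_triplicates(wells, rule=rule, threshold=threshold)
            means[target] = qc.mean_ct if qc.usable else float("nan")
            if not qc.usable:
                flags.append("unusable")
            elif qc.discarded.size:
                flags.append("wells_discarded")
        flag = ("unusable" if "unusable" in flags
                else ("wells_discarded" if flags else "ok"))
        if flag != "unusable":
            try:
                ratio = pfaffl_ratio(means["TEL"], means["ALB"],
                                     curves.get((plate, "TEL")),
                                     curves.get((plate, "ALB")))
            except QuantificationError:
                ratio, flag = float("nan"), "unusable"
        else:
            ratio = float("nan")
        rows.append({
            "subject_id": subject, "plate": plate,
            "mean_ct_tel": means["TEL"], "mean_ct_alb": means["ALB"],
            "stl_ratio": ratio,
            "log_stl": math.log(ratio) if ratio > 0 else float("nan"),
            "qc_flag": flag,
        })
    out = pd.DataFrame(rows)
    out["log_stl_residual"] = residualize_on_plate(out["log_stl"], out["plate"])
    return out
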