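#!/usr/bin/env python
"""Quantify relative sperm telomere length from the raw Ct table.

Fits per-plate standard curves, applies triplicate QC (CV rule, 5%),
forms the Pfaffl Tel/ALB ratio against the 5 ng calibrator, and
residualizes log STL on plates. Writes results/stl.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from telosperm.qpcr import fit_all_standard_curves, quantify

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stl.csv")
    args = ap.parse_args()

    ct = pd.read_csv(args.cohort / "ct.csv")
    curves = fit_all_standard_curves(ct)
    effs = pd.Series({k: c.efficiency for k, c in curves.items()})
    print(f"standard curves fitted: {len(curves)} "
          f"(efficiency {effs.min():.3f}–{effs.max():.3f}, "
          f"median {effs.median():.3f})")

    stl = quantify(ct)
    stl.to_csv(args.out, index=False)
    n_bad = int((stl["qc_flag"] == "unusable").sum())
    n_disc = int((stl["qc_flag"] == "wells_discarded").sum())
    print(f"{len(stl)} subjects quantified; {n_disc} with discarded wells, "
          f"{n_bad} unusable")
    ok = stl[stl["qc_flag"] != "unusable"]
    print(f"STL ratio: median {ok['stl_ratio'].median():.3f}, "
          f"IQR {ok['stl_ratio'].quantile(0.25):.3f}–"
          f"{ok['stl_ratio'].quantile(0.75):.3f}")
    print(f"wrote {args.out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
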