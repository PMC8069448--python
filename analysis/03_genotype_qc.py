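#!/usr/bin/env python
"""Genotype quality control and dosage encoding.

Applies the subject call-rate filter (< 80% discards), tests every panel
SNP for Hardy–Weinberg equilibrium, and encodes effect-allele dosages.
Writes results/dosages.csv and results/qc_report.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from telosperm.genoqc import run_qc
from telosperm.panel import default_panel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    panel = default_panel()
    genotypes = pd.read_csv(args.cohort / "genotypes.csv",
                            dtype=str).set_index("subject_id")
    kept, dosages, report = run_qc(genotypes, panel)

    d = report.to_dict()
    print(f"subjects: {d['n_subjects']}; kept {d['n_kept']} "
          f"({len(d['discarded_subjects'])} below 80% call rate)")
    print(f"mean SNP call rate: {d['mean_snp_call_rate']:.1%}")
    worst = min(report.hwe_results.items(),
                key=lambda kv: kv[1].get("p", 1.0))
    verdict = ("no SNP deviates at alpha = 0.001" if worst[1]["p"] >= 0.001
               else "deviation at alpha = 0.001 — inspect genotyping")
    print(f"HWE: smallest p = {worst[1]['p']:.3f} ({worst[0]}); {verdict}")

    args.out.mkdir(parents=True, exist_ok=True)
    dosages.reset_index().to_csv(args.out / "dosages.csv", index=False)
    with open(args.out / "qc_report.json", "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)
    print(f"wrote {(args.out / 'dosages.csv').relative_to(ROOT)} and "
          f"{(args.out / 'qc_report.json').relative_to(ROOT)}")


if __name__ == "__main__":
    main()
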