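"""End-to-end orchestration: cohort tables → association results.

Glues the stages together the way the analysis drivers and the
acceptance checks run them: qPCR quantification, genotype QC and
encoding, teloscores, ABCD composites, then the association scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import abcd as abcd_mod
from . import associate, genoqc, qpcr, scores
from .panel import SnpDefinition
from .simulate import Cohort


@dataclass
class PipelineResult:
    stl: pd.DataFrame
    kept_genotypes: pd.DataFrame
    dosages: pd.DataFrame
    qc_report: genoqc.QcReport
    score_table: pd.DataFrame
    abcd_table: pd.DataFrame
    results: pd.DataFrame
    skips: list = field(default_factory=list)


def run_pipeline(
    genotypes: pd.DataFrame,
    ct: pd.DataFrame,
    phenotypes: pd.DataFrame,
    panel: list[SnpDefinition],
    centiles=None,
    call_rate_threshold: float = 0.80,
    triplicate_rule: str = "cv_threshold",
    triplicate_threshold: float = 0.05,
    abcd_mode: str = "integer",
    alpha: float = 0.05,
    m: int = 33,
) -> PipelineResult:
    """Run every stage on already-loaded tables and return all artifacts."""
    stl = qpcr.quantify(ct, rule=triplicate_rule,
                        threshold=triplicate_threshold)
    kept, dosages, report = genoqc.run_qc(
        genotypes, panel, call_rate_threshold=call_rate_threshold)
    score_table = scores.compute_scores(dosages, panel)
    abcd_table = abcd_mod.abcd_scores(phenotypes, centiles, mode=abcd_mode)
    results, skips = associate.run_scan(
        pheno=phenotypes, stl=stl, score_table=score_table,
        dosages=dosages, genotypes=kept, abcd_table=abcd_table,
        panel=panel, alpha=alpha, m=m)
    return PipelineResult(stl=stl, kept_genotypes=kept, dosages=dosages,
                          qc_report=report, score_table=score_table,
                          abcd_table=abcd_table, results=results, skips=skips)


def run_pipeline_on_cohort(cohort: Cohort, **kwargs) -> PipelineResult:
    """Convenience wrapper for in-memory synthetic cohorts."""
    pheno = cohort.subjects.merge(cohort.sperm, on="subject_id")
    return run_pipeline(cohort.genotypes, cohort.ct, pheno,
                        panel=cohort.panel, **kwargs)
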