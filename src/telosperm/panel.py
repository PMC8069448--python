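"""SNP panel definitions for the telomere genetic score.

The panel is the single source of truth for effect alleles and per-allele
weights; both are configuration (loaded from YAML), never hard-coded into
scoring logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpDefinition:
    """One panel SNP.

    Parameters
    ----------
    snp_id : str
        rsID.
    gene : str
        Nearest-gene label (annotation only).
    major_allele, minor_allele : str
        Single nucleotides; the minor allele has frequency ``maf``.
    effect_allele : str
        The allele associated with longer telomeres; must be one of the
        two alleles of the SNP.
    weight : float
        Literature per-allele effect on telomere length (arbitrary units);
        used by the weighted score only.
    maf : float
        Minor-allele frequency, in (0, 0.5].
    """

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str
    effect_allele: str
    weight: float
    maf: float

    def __post_init__(self) -> None:
        for a in (self.major_allele, self.minor_allele, self.effect_allele):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"{self.snp_id}: invalid allele {a!r}")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: major and minor alleles identical")
        if self.effect_allele not in (self.major_allele, self.minor_allele):
            raise ValueError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not "
                f"one of {self.major_allele}/{self.minor_allele}"
            )
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside (0, 0.5]")
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.snp_id}: non-finite weight")

    @property
    def effect_allele_frequency(self) -> float:
        """Population frequency of the effect allele."""
        return self.maf if self.effect_allele == self.minor_allele else 1.0 - self.maf

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.major_allele, self.minor_allele)


def load_panel(path: str | Path) -> list[SnpDefinition]:
    """Load a panel from a YAML file with a top-level ``snps`` list."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        entries = raw["snps"]
    except (TypeError, KeyError) as exc:
        raise ValueError(f"{path}: expected a top-level 'snps' list") from exc
    panel = [SnpDefinition(**e) for e in entries]
    if not panel:
        raise ValueError(f"{path}: empty panel")
    ids = [s.snp_id for s in panel]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate snp_ids")
    return panel


def default_panel() -> list[SnpDefinition]:
    """The 11-SNP default panel shipped with the package.

    MAFs and weights in the shipped file are literature-derived placeholders
    (see the YAML header) and are meant to be overridden per study.
    """
    with resources.as_file(
        resources.files("telosperm.data").joinpath("panel.yaml")
    ) as p:
        return load_panel(p)
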