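import numpy as np
import pandas as pd
import pytest

from telosperm.panel import SnpDefinition, default_panel
from telosperm.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    cfg = CohortConfig(n_subjects=150, seed=7, n_plates=4)
    return simulate_cohort(cfg)


@pytest.fixture
def two_snp_panel():
    return [
        SnpDefinition("rs1", "G1", "C", "A", "A", 0.10, 0.30),
        SnpDefinition("rs2", "G2", "T", "G", "T", 0.20, 0.10),
    ]


@pytest.fixture
def genotype_frame(two_snp_panel):
    return pd.DataFrame(
        {"rs1": ["C/C", "C/A", "A/A", None],
         "rs2": ["T/T", "G/T", None, "G/G"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="subject_id"))
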