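"""ABCD sperm-quality banding and composite scores.

Each of four semen parameters (concentration, progressive motility, total
motility, normal morphology) is banded against reference centiles:
A below the 5th, B in [5th, 50th), C in [50th, 95th), D at or above the
95th. Bands map to a pseudo-continuous value (default A..D → 1..4; an
optional interpolated mode adds the within-band position), and the ABCD
score is the sum over the four parameters (range 4–16 in integer mode);
ABCD_mot sums the two motility bands only (2–8).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Parameters entering the total ABCD score (order fixed).
ABCD_PARAMETERS = ("concentration", "progressive_motility",
                   "total_motility", "normal_morphology")
#: Parameters entering ABCD_mot.
ABCD_MOT_PARAMETERS = ("progressive_motility", "total_motility")

_CATEGORIES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class Centiles:
    """Reference 5th/50th/95th centiles for one parameter."""

    p5: float
    p50: float
    p95: float

    def __post_init__(self) -> None:
        if not (self.p5 < self.p50 < self.p95):
            raise ValueError(
                f"centiles must satisfy p5 < p50 < p95, got "
                f"{self.p5}, {self.p50}, {self.p95}")


def load_centiles(path: str | Path) -> dict[str, Centiles]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        entries = raw["centiles"]
    except (TypeError, KeyError) as exc:
        raise ValueError(f"{path}: expected a top-level 'centiles' map") from exc
    return {param: Centiles(**v) for param, v in entries.items()}


def default_centiles() -> dict[str, Centiles]:
    """WHO 2010 semen reference centiles shipped with the package."""
    with resources.as_file(
        resources.files("telosperm.data").joinpath("who2010_centiles.yaml")
    ) as p:
        return load_centiles(p)


def abcd_category(value: float, centiles: Centiles) -> str:
    """Band a value: A < p5 ≤ B < p50 ≤ C < p95 ≤ D (half-open bands)."""
    if not np.isfinite(value):
        raise ValueError("cannot categorize a non-finite value")
    if value < centiles.p5:
        return "A"
    if value < centiles.p50:
        return "B"
    if value < centiles.p95:
        return "C"
    return "D"


def abcd_pseudo_continuous(
    value: float, centiles: Centiles, mode: str = "integer"
) -> float:
    """Pseudo-continuous band score in [1, 5).

    ``integer`` maps A→1, B→2, C→3, D→4. ``interpolated`` adds the linear
    position within the band (A: value/p5 from 0; D: 1 − p95/value,
    approaching 1 from 0 at the band edge), so it floors to the integer
    score and is strictly monotone in the parameter.
    """
    cat = abcd_category(value, centiles)
    base = float(_CATEGORIES.index(cat) + 1)
    if mode == "integer":
        return base
    if mode != "interpolated":
        raise ValueError(f"unknown mode {mode!r}")
    eps = 1e-12
    if cat == "A":
        frac = max(value, 0.0) / centiles.p5
    elif cat == "B":
        frac = (value - centiles.p5) / (centiles.p50 - centiles.p5)
    elif cat == "C":
        frac = (value - centiles.p50) / (centiles.p95 - centiles.p50)
    else:
        frac = 1.0 - centiles.p95 / value if value > 0 else 0.0
    return base + min(max(frac, 0.0), 1.0 - eps)


def abcd_scores(
    phenotypes: pd.DataFrame,
    centiles: dict[str, Centiles] | None = None,
    mode: str = "integer",
) -> pd.DataFrame:
    """Band all subjects and compute ABCD / ABCD_mot composites.

    ``phenotypes`` must carry subject_id and the four banded parameters.
    A subject missing any required parameter gets NaN for every composite
    that needs it. Output columns: per-parameter ``<param>_category`` and
    ``<param>_value``, plus ``abcd_total``, ``abcd_mot`` and ``mode``.
    """
    centiles = centiles if centiles is not None else default_centiles()
    missing = [p for p in ABCD_PARAMETERS if p not in centiles]
    if missing:
        raise ValueError(f"centiles missing for parameters: {missing}")
    out = pd.DataFrame({"subject_id": phenotypes["subject_id"]})
    values = {}
    for param in ABCD_PARAMETERS:
        c = centiles[param]
        vals = phenotypes[param].astype(float)
        cats, nums = [], []
        for v in vals:
            if np.isfinite(v):
                cats.append(abcd_category(v, c))
                nums.append(abcd_pseudo_continuous(v, c, mode=mode))
            else:
                cats.append(None)
                nums.append(np.nan)
        out[f"{param}_category"] = cats
        out[f"{param}_value"] = nums
        values[param] = np.asarray(nums)
    out["abcd_total"] = np.sum([values[p] for p in ABCD_PARAMETERS], axis=0)
    out["abcd_mot"] = np.sum([values[p] for p in ABCD_MOT_PARAMETERS], axis=0)
    out["mode"] = mode
    return out
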