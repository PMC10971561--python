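"""Field-survey arithmetic: leaf-loss rate and four-level damage grading.

A surveyed larch is graded by its leaf-loss rate DR, the percentage of
damaged needles among all needles, ``DR = 100 * L_d / (L_h + L_d)``.
Four damage levels are assigned by DR band:

=====  ========  ==============
level  name      DR band (%)
=====  ========  ==============
1      Healthy   [0, 5]
2      Mild      (5, 30]
3      Moderate  (30, 70]
4      Severe    (70, 100]
=====  ========  ==============

The printed bands are integer (0-5, 6-30, 31-70, 71-100); the half-open
continuum convention above keeps every printed integer in its printed band
while covering fractional rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVEL_NAMES",
    "DR_BAND_EDGES",
    "SurveyRecord",
    "leaf_loss_rate",
    "classify_level",
    "aggregate_branches",
    "read_survey_csv",
    "write_survey_csv",
]

LEVEL_NAMES = {1: "Healthy", 2: "Mild", 3: "Moderate", 4: "Severe"}

#: Upper (inclusive) DR edge of levels 1..3; level 4 runs to 100.
DR_BAND_EDGES = (5.0, 30.0, 70.0)


@dataclass(frozen=True)
class SurveyRecord:
    """One surveyed tree: needle counts, leaf-loss rate and damage level."""

    tree_id: int
    L_h: int
    L_d: int
    DR: float
    level: int

    def __post_init__(self) -> None:
        if self.L_h < 0 or self.L_d < 0 or self.L_h + self.L_d == 0:
            raise ValueError(
                f"tree {self.tree_id}: needle counts must be non-negative "
                f"with a positive total (got L_h={self.L_h}, L_d={self.L_d})"
            )
        expected = leaf_loss_rate(self.L_h, self.L_d)
        if abs(self.DR - expected) > 1e-6:
            raise ValueError(
                f"tree {self.tree_id}: DR={self.DR} inconsistent with counts "
                f"(expected {expected})"
            )
        if self.level != classify_level(self.DR):
            raise ValueError(
                f"tree {self.tree_id}: level {self.level} inconsistent with "
                f"DR={self.DR}"
            )

    @classmethod
    def from_counts(cls, tree_id: int, L_h: int, L_d: int) -> "SurveyRecord":
        dr = leaf_loss_rate(L_h, L_d)
        return cls(tree_id=tree_id, L_h=L_h, L_d=L_d, DR=dr,
                   level=classify_level(dr))


def leaf_loss_rate(L_h: float, L_d: float) -> float:
    """Leaf-loss rate DR in percent from healthy/damaged needle counts."""
    if L_h < 0 or L_d < 0:
        raise ValueError("needle counts must be non-negative")
    total = L_h + L_d
    if total == 0:
        raise ValueError("total needle count must be positive")
    return 100.0 * L_d / total


def classify_level(DR: float) -> int:
    """Damage level 1-4 from leaf-loss rate DR (percent)."""
    if not np.isfinite(DR) or DR < 0 or DR > 100:
        raise ValueError(f"DR must lie in [0, 100], got {DR!r}")
    for level, edge in enumerate(DR_BAND_EDGES, start=1):
        if DR <= edge:
            return level
    return 4


def aggregate_branches(branch_rates: Sequence[float]) -> float:
    """Tree-level leaf-loss rate as the mean of per-branch rates."""
    rates = np.asarray(branch_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("branch_rates must be non-empty")
    if np.any(rates < 0) or np.any(rates > 100):
        raise ValueError("branch rates must lie in [0, 100]")
    return float(rates.mean())


def write_survey_csv(records: Iterable[SurveyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "healthy_needles": r.L_h,
                "damaged_needles": r.L_d,
                "DR": r.DR,
                "level": r.level,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_survey_csv(path: str | Path) -> list[SurveyRecord]:
    df = pd.read_csv(path)
    return [
        SurveyRecord.from_counts(
            int(row.tree_id), int(row.healthy_needles), int(row.damaged_needles)
        )
        for row in df.itertuples()
    ]
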