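"""Assay arithmetic: invasiveness from field counts, proliferation, doubling time.

Invasion assays image five random fields at the underside of the
Boyden-chamber membrane; the total invading-cell number is extrapolated
from the imaged area by an area factor (total membrane area over one
field's area) and divided by the number of cells seeded.  Proliferation
uses the resazurin (alamarBlue) reduction score and fold changes between
timepoints to obtain doubling times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FieldCounts",
    "ProliferationReading",
    "InvasivenessEstimate",
    "DoublingTime",
    "area_factor",
    "invasiveness_from_counts",
    "alamarblue_score",
    "doubling_time",
]


@dataclass(frozen=True)
class FieldCounts:
    """Invading-cell counts per imaged field plus assay geometry.

    frame_side_mm is the side length of the (square) imaged field;
    total_area_cm2 the under-membrane area; seeded_n the cells seeded.
    """

    counts: Sequence[int]
    frame_side_mm: float = 1.18
    total_area_cm2: float = 0.3
    seeded_n: int = 45_000

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.size == 0:
            raise ValueError("need at least one field count")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if self.frame_side_mm <= 0:
            raise ValueError("frame_side_mm must be positive")
        if self.total_area_cm2 <= 0:
            raise ValueError("total_area_cm2 must be positive")
        if self.seeded_n <= 0:
            raise ValueError("seeded_n must be positive")


@dataclass(frozen=True)
class ProliferationReading:
    """Blank-subtracted absorbances and extinction coefficients.

    o1, o2 are the molar extinction coefficients of the oxidized reagent
    at 570 nm and 600 nm (1/M/cm); they are required inputs — vendor
    constants vary by reagent documentation, so no defaults are baked in.
    """

    a570: float
    a600: float
    o1: float
    o2: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.o1 <= 0 or self.o2 <= 0:
            raise ValueError("extinction coefficients must be positive")


@dataclass(frozen=True)
class InvasivenessEstimate:
    v: float
    flagged: bool  # True when the estimate exceeds 1 (counting noise)


@dataclass(frozen=True)
class DoublingTime:
    hours: float
    shrinking: bool  # True when the population declined (negative doubling time)


MM2_PER_CM2 = 100.0


def area_factor(fc: FieldCounts) -> float:
    """Total membrane area over one imaged field's area (dimensionless).

    total_area_cm2 * 100 mm^2/cm^2 / frame_side_mm^2.  With a 1.18 mm
    frame and 0.3 cm^2 membrane this is 21.5456 (commonly quoted as 21.54).
    """
    return fc.total_area_cm2 * MM2_PER_CM2 / fc.frame_side_mm**2


def invasiveness_from_counts(fc: FieldCounts) -> InvasivenessEstimate:
    """Population invasiveness from per-field counts.

    mean(counts) * area_factor / seeded_n.  Values above 1 are flagged
    but not clamped — they preserve the raw counting evidence.
    """
    v = float(np.mean(fc.counts)) * area_factor(fc) / fc.seeded_n
    return InvasivenessEstimate(v=v, flagged=v > 1.0)


def alamarblue_score(r: ProliferationReading) -> float:
    """Reduction score S = o2 * a570 - o1 * a600 (sign-preserving)."""
    return r.o2 * r.a570 - r.o1 * r.a600


def doubling_time(t1: float, t2: float, f1: float, f2: float) -> DoublingTime:
    """Doubling time from relative-proliferation fold changes.

    Td = (t2 - t1) * ln 2 / ln(f2 / f1).  A declining population
    (f2 < f1) yields a negative Td, returned with a shrinking flag.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if f1 <= 0 or f2 <= 0:
        raise ValueError("fold changes must be positive")
    if f2 == f1:
        raise ValueError("no growth between timepoints; doubling time undefined")
    td = (t2 - t1) * np.log(2.0) / np.log(f2 / f1)
    return DoublingTime(hours=float(td), shrinking=f2 < f1)
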