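"""Summary statistics of single-cell fluorescence samples.

MFI and CV on the linear axis, mean/SD on the log10 axis, Pearson
correlations of per-dose differentials between clone pairs, and detection
of "decoupled noise points" (conditions with matched mean expression but
different CV, the configurations that let noise effects be tested
independently of the mean).

Conventions: population SD (divide by n) throughout; CV is stored as a
fraction and rendered as % only at presentation; non-positive fluorescence
values are excluded with a logged count rather than shifted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SampleSummary",
    "summarize",
    "log10_transform",
    "delta_correlation",
    "find_decoupled_pairs",
]


@dataclass(frozen=True)
class SampleSummary:
    """Per-condition summary of a fluorescence sample.

    mfi and cv are computed on the linear axis; log10_mean/log10_sd on the
    log10 axis of the positive values.  ``n_dropped`` counts excluded
    non-positive values.
    """

    mfi: float
    cv: float
    n: int
    log10_mean: float
    log10_sd: float
    n_dropped: int = 0
    clone: str | None = None
    dose: float | None = None
    compartment: str | None = None
    replicate: int | None = None

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.cv


def _values_of(sample) -> np.ndarray:
    return np.asarray(getattr(sample, "values", sample), dtype=float)


def summarize(sample) -> SampleSummary:
    """MFI, CV and log10 statistics of an expression sample.

    Non-positive values are excluded (with their count recorded) before
    any statistic is computed; an all-non-positive sample is an error.
    """
    raw = _values_of(sample)
    values = raw[raw > 0]
    n_dropped = int(raw.size - values.size)
    if values.size == 0:
        raise ValueError("no positive fluorescence values to summarize")
    mfi = float(values.mean())
    cv = float(values.std(ddof=0) / mfi)
    z = np.log10(values)
    return SampleSummary(
        mfi=mfi,
        cv=cv,
        n=int(values.size),
        log10_mean=float(z.mean()),
        log10_sd=float(z.std(ddof=0)),
        n_dropped=n_dropped,
        clone=getattr(sample, "clone", None),
        dose=getattr(sample, "dose", None),
        compartment=getattr(sample, "compartment", None),
        replicate=getattr(sample, "replicate", None),
    )


def log10_transform(sample) -> tuple[np.ndarray, int]:
    """log10 of the positive values and the count of dropped entries."""
    raw = _values_of(sample)
    values = raw[raw > 0]
    if values.size == 0:
        raise ValueError("no positive fluorescence values to transform")
    return np.log10(values), int(raw.size - values.size)


@dataclass(frozen=True)
class DeltaCorrelation:
    """Pearson correlations of per-dose differentials vs Δinvasiveness."""

    r_cv: float
    p_cv: float
    r_mean: float
    p_mean: float
    n: int


def delta_correlation(pairs: Sequence[tuple]) -> DeltaCorrelation:
    """Correlate ΔCV and ΔMean with ΔInvasiveness across doses.

    Each element of ``pairs`` is (ΔCV, ΔMean, ΔInvasiveness) at one dose,
    with Δ = high-noise clone minus low-noise clone.  Returns Pearson r
    and two-sided t-distributed p for ΔCV vs ΔInvasiveness and for
    ΔMean vs ΔInvasiveness.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (dCV, dMean, dInvasiveness) triples")
    d_cv, d_mean, d_inv = arr.T
    for name, x in (("dCV", d_cv), ("dMean", d_mean), ("dInvasiveness", d_inv)):
        if np.ptp(x) == 0:
            raise ValueError(f"{name} has zero variance; correlation undefined")
    r_cv, p_cv = stats.pearsonr(d_cv, d_inv)
    r_mean, p_mean = stats.pearsonr(d_mean, d_inv)
    return DeltaCorrelation(r_cv=float(r_cv), p_cv=float(p_cv),
                            r_mean=float(r_mean), p_mean=float(p_mean), n=arr.shape[0])


def find_decoupled_pairs(
    summaries: Mapping[object, SampleSummary],
    mean_tol: float = 0.1,
    cv_gap: float = 0.1,
) -> list[tuple]:
    """Condition pairs with matched MFI but clearly different CV.

    A pair (a, b) qualifies when |mfi_a / mfi_b - 1| <= mean_tol and
    |cv_a - cv_b| >= cv_gap.  Returns the list of qualifying key pairs
    (possibly empty).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries")
    keys = list(summaries)
    out = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            a, b = summaries[ka], summaries[kb]
            ratio = a.mfi / b.mfi if b.mfi else np.inf
            if abs(ratio - 1.0) <= mean_tol and abs(a.cv - b.cv) >= cv_gap:
                out.append((ka, kb))
    return out
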