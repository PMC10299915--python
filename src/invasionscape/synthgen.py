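"""Synthetic single-cell expression data with dose- and noise-tuned structure.

Emulates flow-cytometry measurements of clones carrying a doxycycline-
tunable expression circuit: per-dose fluorescence histograms that are
approximately Gaussian on the log10 axis, a monotone Hill-type mean dose
response reaching up to 30-fold induction, low-noise vs high-noise clones
with matched means ("decoupled noise points"), and seeded/invaded sample
pairs produced by Bernoulli thinning under a known ground-truth invasion
landscape.  The generator is the benchmark source for every inference
routine in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .landscape import InvasivenessRecord, Landscape

__all__ = [
    "CloneSpec",
    "DoseGrid",
    "ExpressionSample",
    "BenchmarkDataset",
    "DEFAULT_DOSES",
    "hill_mean",
    "sample_cells",
    "generate_benchmark_dataset",
    "lognormal_cv",
    "expected_log10_mean",
    "valley_truth",
    "up_down_up_truth",
]

#: Dox concentrations (ng/ml) of the standard dose-response sweep.
DEFAULT_DOSES = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 100.0)

LN10 = np.log(10.0)


@dataclass(frozen=True)
class CloneSpec:
    """Hill dose response plus noise profile defining a synthetic clone.

    Parameters
    ----------
    basal_mfi : float
        Uninduced mean fluorescence intensity (linear a.u.).
    fold : float
        Ratio of fully induced to basal mean (>= 1).
    ec50 : float
        Dox concentration at half-maximal induction (ng/ml).
    hill_n : float
        Hill coefficient of the dose response.
    sigma_log10 : float or mapping dose -> float
        SD of log10 fluorescence per dose (log10 a.u.); a constant applies
        at every dose.
    label : str
        Clone identifier (e.g. 'BL' for the low-noise clone).
    """

    basal_mfi: float = 100.0
    fold: float = 30.0
    ec50: float = 0.5
    hill_n: float = 1.2
    sigma_log10: float | Mapping[float, float] = 0.15
    label: str = "clone"

    def __post_init__(self) -> None:
        if self.basal_mfi <= 0:
            raise ValueError("basal_mfi must be positive")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        sigmas = (self.sigma_log10.values() if isinstance(self.sigma_log10, Mapping)
                  else [self.sigma_log10])
        if any(s <= 0 for s in sigmas):
            raise ValueError("all sigma_log10 values must be positive")

    def sigma(self, dose: float) -> float:
        """Noise level (SD of log10 fluorescence) at a given dose."""
        if isinstance(self.sigma_log10, Mapping):
            try:
                return float(self.sigma_log10[dose])
            except KeyError:
                raise KeyError(f"no sigma_log10 entry for dose {dose} ng/ml") from None
        return float(self.sigma_log10)


#: Default low-noise and high-noise clones with matched dose responses.
LOW_NOISE_CLONE = CloneSpec(sigma_log10=0.15, label="BL")
HIGH_NOISE_CLONE = CloneSpec(sigma_log10=0.30, label="BH")


@dataclass(frozen=True)
class DoseGrid:
    """Ordered doxycycline concentrations (ng/ml) of a dose sweep."""

    doses: Sequence[float] = DEFAULT_DOSES

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("doses must be a non-empty 1-D sequence")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        object.__setattr__(self, "doses", tuple(float(x) for x in d))

    def __iter__(self):
        return iter(self.doses)

    def __len__(self):
        return len(self.doses)


@dataclass
class ExpressionSample:
    """Single-cell linear fluorescence values for one condition.

    Attributes
    ----------
    values : ndarray
        Linear fluorescence (a.u.), one entry per cell.
    clone : str
    dose : float
        Dox concentration (ng/ml).
    compartment : {'seeded', 'invaded'}
    replicate : int
    """

    values: np.ndarray
    clone: str = "clone"
    dose: float = 0.0
    compartment: str = "seeded"
    replicate: int = 0

    def __post_init__(self) -> None:
        # zero-length samples are legal (an invaded compartment can be empty
        # when nothing invades); operations that need data raise instead
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all fluorescence values must be finite")
        if self.compartment not in ("seeded", "invaded"):
            raise ValueError("compartment must be 'seeded' or 'invaded'")

    def __len__(self) -> int:
        return self.values.size

    def log10_values(self) -> np.ndarray:
        """log10 of the positive values (non-positive entries dropped)."""
        return np.log10(self.values[self.values > 0])


def hill_mean(d: float, spec: CloneSpec) -> float:
    """Mean linear fluorescence at dox dose ``d``.

    M(d) = basal * (1 + (fold - 1) * d^n / (ec50^n + d^n)); monotone
    nondecreasing, M(0) = basal, M(inf) = basal * fold.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(divide="ignore"):
        dn = np.where(d > 0, d**spec.hill_n, 0.0)
    occ = dn / (spec.ec50**spec.hill_n + dn)
    out = spec.basal_mfi * (1.0 + (spec.fold - 1.0) * occ)
    return float(out) if out.ndim == 0 else out


def lognormal_cv(sigma_log10: float) -> float:
    """Linear-scale CV of a distribution lognormal in base 10.

    If log10 X ~ N(m, s^2) then CV(X) = sqrt(exp((s ln 10)^2) - 1),
    independent of m.
    """
    return float(np.sqrt(np.expm1((sigma_log10 * LN10) ** 2)))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_cells(
    spec: CloneSpec,
    d: float,
    n: int,
    seed,
    replicate: int = 0,
    compartment: str = "seeded",
) -> ExpressionSample:
    """Draw ``n`` single-cell fluorescence values at dose ``d``.

    log10 values are Gaussian with SD sigma_log10(d) and location chosen so
    that the LINEAR mean equals hill_mean(d):

        m = log10 M(d) - sigma^2 ln(10) / 2,

    the lognormal mean correction (MFI is reported on the linear axis while
    the histograms are Gaussian in log space).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    sigma = spec.sigma(d)
    m = np.log10(hill_mean(d, spec)) - sigma**2 * LN10 / 2.0
    z = rng.normal(m, sigma, size=int(n))
    return ExpressionSample(values=10.0**z, clone=spec.label, dose=float(d),
                            compartment=compartment, replicate=replicate)


def expected_log10_mean(spec: CloneSpec, dose: float) -> float:
    """Gaussian location of log10 fluorescence at a dose (lognormal-corrected)."""
    sigma = spec.sigma(dose)
    return float(np.log10(hill_mean(dose, spec)) - sigma**2 * LN10 / 2.0)


def valley_truth(
    spec: CloneSpec,
    dose: float = 0.5,
    depth: float = 0.1,
    shoulder_w: float = 0.6,
    shoulder_sd: float = 2.5,
    halfwidth_sd: float = 8.0,
    grid_size: int = 512,
) -> Landscape:
    """Quadratic-valley ground truth centred on the seeded population.

    w dips to ``depth`` at the seeded log10 mean, rises quadratically to
    ``shoulder_w`` at ``shoulder_sd`` seeded SDs from the centre, and is
    held at the shoulder value beyond — the canonical disruptive-selection
    benchmark for landscape-recovery tests.
    """
    z0 = expected_log10_mean(spec, dose)
    sigma = spec.sigma(dose)
    a = (shoulder_w - depth) / (shoulder_sd * sigma) ** 2
    half = halfwidth_sd * sigma

    def fn(z):
        return np.minimum(depth + a * (z - z0) ** 2, shoulder_w)

    return Landscape.from_callable(fn, z0 - half, z0 + half, grid_size,
                                   meta={"shape": "valley", "center": z0})


def up_down_up_truth(
    z_lo: float,
    z_hi: float,
    grid_size: int = 512,
) -> Landscape:
    """Nonmonotone (rise, dip, rise) ground truth over [z_lo, z_hi].

    A sigmoidal rise followed by a Gaussian dip and a second rise —
    the qualitative shape of a nonmonotone invasion landscape with a
    valley at intermediate expression.
    """
    span = z_hi - z_lo
    c1 = z_lo + 0.30 * span   # first rise midpoint
    c2 = z_lo + 0.55 * span   # valley centre
    c3 = z_lo + 0.80 * span   # second rise midpoint

    def fn(z):
        rise1 = 0.45 / (1.0 + np.exp(-10.0 / span * (z - c1) * 4))
        dip = -0.40 * np.exp(-((z - c2) ** 2) / (2 * (0.07 * span) ** 2))
        rise2 = 0.35 / (1.0 + np.exp(-10.0 / span * (z - c3) * 4))
        return np.clip(0.15 + rise1 + dip + rise2, 0.0, 1.0)

    return Landscape.from_callable(fn, z_lo, z_hi, grid_size,
                                   meta={"shape": "up_down_up"})


@dataclass
class BenchmarkDataset:
    """Seeded/invaded sample pairs with the ground truth that produced them."""

    seeded: list[ExpressionSample]
    invaded: list[ExpressionSample]
    records: list[InvasivenessRecord]
    truth: Landscape
    spec: CloneSpec
    grid: DoseGrid
    seed: int

    def pairs(self):
        """Iterate (seeded, invaded, record) triples in generation order."""
        return zip(self.seeded, self.invaded, self.records)

    def dose_sweep(self):
        """(seeded sample, InvasivenessRecord) pairs for global landscape fits."""
        return list(zip(self.seeded, self.records))


def generate_benchmark_dataset(
    spec: CloneSpec,
    grid: DoseGrid,
    truth: Landscape,
    n_per_dose: int = 20_000,
    reps: int = 1,
    seed: int = 0,
    max_uncovered: float = 0.05,
) -> BenchmarkDataset:
    """Generate a seeded/invaded benchmark with known invasion landscape.

    For every (dose, replicate) a seeded sample is drawn, each cell invades
    with probability ``truth(z)`` (independent Bernoulli thinning of the
    log10 level z), and the realized invasiveness is recorded.  The truth
    landscape is carried alongside for recovery tests.

    Raises
    ------
    ValueError
        If more than ``max_uncovered`` of the seeded probability mass falls
        outside the truth landscape's grid at any dose.
    """
    master = np.random.SeedSequence(int(seed))
    children = master.spawn(len(grid.doses) * reps * 2)
    seeded_list: list[ExpressionSample] = []
    invaded_list: list[ExpressionSample] = []
    records: list[InvasivenessRecord] = []
    k = 0
    z_lo, z_hi = truth.z_grid[0], truth.z_grid[-1]
    for dose in grid.doses:
        for rep in range(reps):
            rng_draw = np.random.default_rng(children[k]); k += 1
            rng_thin = np.random.default_rng(children[k]); k += 1
            seeded = sample_cells(spec, dose, n_per_dose, rng_draw,
                                  replicate=rep, compartment="seeded")
            z = seeded.log10_values()
            uncovered = float(np.mean((z < z_lo) | (z > z_hi)))
            if uncovered > max_uncovered:
                raise ValueError(
                    f"landscape grid [{z_lo:.3g}, {z_hi:.3g}] leaves {uncovered:.1%} of the "
                    f"seeded mass at dose {dose} ng/ml uncovered (sample spans "
                    f"[{z.min():.3g}, {z.max():.3g}])")
            invade = rng_thin.uniform(size=z.size) < truth(z)
            v = float(invade.mean())
            records.append(InvasivenessRecord(dose=dose, v=v, replicate=rep))
            seeded_list.append(seeded)
            invaded_list.append(ExpressionSample(
                values=seeded.values[invade], clone=spec.label, dose=dose,
                compartment="invaded", replicate=rep))
    return BenchmarkDataset(seeded=seeded_list, invaded=invaded_list, records=records,
                            truth=truth, spec=spec, grid=grid, seed=int(seed))
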