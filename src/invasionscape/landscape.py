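"""Single-cell invasion landscapes.

The invasion landscape ``w(z)`` gives the probability that a cell whose
log10 expression level is ``z`` crosses the Boyden-chamber membrane during
one invasion assay.  Because invasion acts as Bernoulli thinning of the
seeded population, the densities of seeded and invaded cells obey

    f_inv(z) = w(z) * f_seed(z) / V,

where ``V`` is the population invasiveness (fraction of seeded cells that
invade).  This module provides the :class:`Landscape` container, the
ratio estimator that inverts the thinning identity for one condition
(:func:`infer_ratio`), a global piecewise-linear fit across a dose sweep
(:func:`infer_global`), the analytic expectation of the Monte Carlo assay
(:func:`expected_invasiveness`), a two-dimensional (mean, CV) biharmonic
surface (:func:`interpolate_2d`), and local slope/curvature classification
(:func:`local_geometry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import RBFInterpolator
from scipy.optimize import lsq_linear
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "Landscape",
    "InvasivenessRecord",
    "Surface2D",
    "GeometryReport",
    "infer_ratio",
    "infer_global",
    "expected_invasiveness",
    "slope_sign_pattern",
    "interpolate_2d",
    "local_geometry",
]


@dataclass(frozen=True)
class InvasivenessRecord:
    """Population invasiveness measured for one condition.

    Parameters
    ----------
    dose : float
        Doxycycline concentration (ng/ml).
    v : float
        Invasiveness: invading / originally seeded cells, in [0, 1].
    replicate : int
        Replicate index.
    """

    dose: float
    v: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"invasiveness must lie in [0, 1], got {self.v}")


@dataclass
class Landscape:
    """Per-cell invasion probability as a function of log10 expression.

    Attributes
    ----------
    z_grid : ndarray
        Strictly increasing log10 fluorescence grid (log10 a.u.).
    w : ndarray
        Invasion probability at each grid point, within [0, 1].
    support_mask : ndarray of bool
        True where the estimate is trusted (enough seeded density).
    meta : dict
        Provenance: estimator, bandwidth, fit residuals, ...
    """

    z_grid: np.ndarray
    w: np.ndarray
    support_mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z_grid.ndim != 1 or self.z_grid.size < 2:
            raise ValueError("z_grid must be a 1-D array with at least 2 points")
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        if self.w.shape != self.z_grid.shape:
            raise ValueError("w and z_grid must have the same shape")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ValueError("w must lie within [0, 1]")
        self.w = np.clip(self.w, 0.0, 1.0)
        if self.support_mask is None:
            self.support_mask = np.ones_like(self.z_grid, dtype=bool)
        self.support_mask = np.asarray(self.support_mask, dtype=bool)
        if self.support_mask.shape != self.z_grid.shape:
            raise ValueError("support_mask must match z_grid")

    # -- evaluation ---------------------------------------------------

    def __call__(self, z) -> np.ndarray:
        """Evaluate w at log10 levels ``z``.

        Linear interpolation between grid points; outside the grid the
        boundary value is held constant (the ratio is undefined where no
        seeded cells were observed, so the nearest trusted value is used).
        """
        return np.interp(np.asarray(z, dtype=float), self.z_grid, self.w)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_callable(
        cls,
        fn: Callable[[np.ndarray], np.ndarray],
        z_min: float,
        z_max: float,
        n: int = 256,
        meta: dict | None = None,
    ) -> "Landscape":
        """Tabulate a ground-truth landscape function on a regular grid."""
        z = np.linspace(z_min, z_max, n)
        w = np.clip(np.asarray(fn(z), dtype=float), 0.0, 1.0)
        return cls(z, w, meta=dict(meta or {}, source="callable"))

    @classmethod
    def flat(cls, c: float, z_min: float = 0.0, z_max: float = 5.0, n: int = 256) -> "Landscape":
        return cls.from_callable(lambda z: np.full_like(z, float(c)), z_min, z_max, n)


@dataclass
class Surface2D:
    """Biharmonic (thin-plate) invasiveness surface over (log10 mean, CV)."""

    points: np.ndarray          # (n, 2) input locations
    values: np.ndarray          # (n,) invasiveness at the inputs
    mean_grid: np.ndarray
    cv_grid: np.ndarray
    surface: np.ndarray         # (len(cv_grid), len(mean_grid))
    _rbf: RBFInterpolator
    _hull: Delaunay

    def query(self, mean: float, cv: float) -> tuple[float, bool]:
        """Interpolated invasiveness at (mean, cv) and an extrapolation flag."""
        pt = np.array([[mean, cv]], dtype=float)
        value = float(self._rbf(pt)[0])
        extrapolated = self._hull.find_simplex(pt)[0] < 0
        return value, bool(extrapolated)


@dataclass(frozen=True)
class GeometryReport:
    """Local quadratic geometry of a landscape around a focal level."""

    kind: str                  # upslope | downslope | peak | valley | flat
    slope: float               # dw/dz at z0 (per log10 a.u.)
    curvature: float           # d2w/dz2 at z0
    z0: float
    window: float


def _positive_log10(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return np.log10(values[values > 0])


def _as_log10(sample) -> np.ndarray:
    """Accept an ExpressionSample (linear a.u.) or an array of log10 values."""
    values = getattr(sample, "values", None)
    if values is not None:
        z = _positive_log10(values)
    else:
        z = np.asarray(sample, dtype=float)
    if z.size == 0:
        raise ValueError("no usable (positive, finite) expression values")
    return z


def _shared_bandwidth_kdes(z_seed: np.ndarray, z_inv: np.ndarray, bandwidth):
    """Gaussian KDEs for both compartments with one absolute bandwidth.

    Using a single bandwidth h (on the log10 axis) for both densities
    avoids spurious structure in their ratio.  ``bandwidth`` may be
    'silverman' (computed from the seeded sample) or a float in log10 a.u.
    """
    if bandwidth == "silverman" or bandwidth is None:
        kde_seed = stats.gaussian_kde(z_seed, bw_method="silverman")
        h = kde_seed.factor * z_seed.std(ddof=0)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        kde_seed = stats.gaussian_kde(z_seed, bw_method=h / z_seed.std(ddof=0))
    sd_inv = z_inv.std(ddof=0)
    if sd_inv == 0:
        sd_inv = h  # degenerate invaded sample: fall back to bandwidth-width kernel
    kde_inv = stats.gaussian_kde(z_inv, bw_method=h / sd_inv)
    return kde_seed, kde_inv, h


def infer_ratio(
    seeded,
    invaded,
    v: float,
    bandwidth="silverman",
    support_frac: float | None = None,
    se_max: float = 0.015,
    grid_size: int = 256,
) -> Landscape:
    """Infer w(z) from one seeded/invaded pair via the thinning identity.

    Computes ``w_hat(z) = v * f_inv(z) / f_seed(z)`` on a grid spanning the
    0.1-99.9 percentile range of the seeded log10 values, with both
    densities estimated by Gaussian KDE at a shared bandwidth, and clips to
    [0, 1].

    The support mask marks where the estimate is statistically trusted.
    By default a grid point is trusted when the estimator's (binomial)
    standard error sqrt(w(1-w)/n_eff) is at most ``se_max``, with
    n_eff = n_seed * h * f_seed * 2*sqrt(pi) the effective kernel sample
    size; this region grows with sample size, so the recovery error on
    support vanishes as n grows.  Passing ``support_frac`` switches to the
    simpler rule of thresholding the seeded density at that fraction of
    its peak.  Outside support the boundary value is held (for
    simulation) but flagged untrusted.

    Parameters
    ----------
    seeded, invaded : ExpressionSample or array of log10 values
    v : float
        Measured population invasiveness for this condition, in (0, 1].
    bandwidth : 'silverman' or float
        Kernel bandwidth on the log10 axis, shared by both compartments.
    support_frac : float, optional
        Seeded-density threshold (fraction of the density peak); overrides
        the standard-error rule when given.
    se_max : float
        Maximum tolerated standard error of w_hat inside support.
    """
    z_seed = _as_log10(seeded)
    inv_raw = getattr(invaded, "values", None)
    if inv_raw is not None:
        z_inv = _positive_log10(inv_raw)          # ExpressionSample: linear a.u.
    else:
        z_inv = np.asarray(invaded, dtype=float)  # bare array: already log10
    if not 0.0 <= v <= 1.0:
        raise ValueError("invasiveness v must lie in [0, 1]")
    if v == 0.0:
        if z_inv.size > 0:
            raise ValueError("v = 0 is inconsistent with a non-empty invaded sample")
        lo, hi = np.percentile(z_seed, [0.1, 99.9])
        grid = np.linspace(lo, hi, grid_size)
        return Landscape(grid, np.zeros(grid_size), meta={"estimator": "ratio", "v": 0.0})
    if z_inv.size == 0:
        raise ValueError("invaded sample is empty but v > 0")

    lo, hi = np.percentile(z_seed, [0.1, 99.9])
    grid = np.linspace(lo, hi, grid_size)
    kde_seed, kde_inv, h = _shared_bandwidth_kdes(z_seed, z_inv, bandwidth)
    f_seed = kde_seed(grid)
    f_inv = kde_inv(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(f_seed > 0, v * f_inv / f_seed, 0.0)
    w = np.clip(w, 0.0, 1.0)
    n_eff = z_seed.size * h * f_seed * 2.0 * np.sqrt(np.pi)
    if support_frac is not None:
        support = f_seed >= support_frac * f_seed.max()
    else:
        # binomial variance floored at its w=0.1 value so a noisy low
        # estimate cannot sneak a sparse region into the trusted set
        se = np.sqrt(np.maximum(w * (1.0 - w), 0.09) / np.maximum(n_eff, 1e-12))
        support = (se <= se_max) & (n_eff >= 50.0)
    if not support.any():
        raise ValueError("no grid point reaches the trust threshold; "
                         "increase the sample size or relax the support rule")
    # hold the boundary value of the supported region outside support
    idx = np.flatnonzero(support)
    w[: idx[0]] = w[idx[0]]
    w[idx[-1] + 1:] = w[idx[-1]]
    meta = {"estimator": "ratio", "bandwidth": h, "v": float(v),
            "n_seeded": int(z_seed.size), "n_invaded": int(z_inv.size),
            "support_rule": ("density_frac" if support_frac is not None else "se"),
            "n_eff": n_eff}
    return Landscape(grid, w, support_mask=support, meta=meta)


def _hat_basis(z: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Piecewise-linear (hat function) design matrix, shape (len(z), len(nodes))."""
    z = np.clip(z, nodes[0], nodes[-1])
    basis = np.zeros((z.size, nodes.size))
    for k, node in enumerate(nodes):
        left = nodes[k - 1] if k > 0 else node
        right = nodes[k + 1] if k < nodes.size - 1 else node
        up = np.zeros_like(z)
        if node > left:
            sel = (z >= left) & (z <= node)
            up[sel] = (z[sel] - left) / (node - left)
        else:
            up[z <= node] = 1.0
        down = np.zeros_like(z)
        if right > node:
            sel = (z > node) & (z <= right)
            down[sel] = (right - z[sel]) / (right - node)
        else:
            down[z > node] = 1.0
        basis[:, k] = up + down
    return basis


def _solve_bounded_ridge(A, v, D2, ridge):
    n_nodes = A.shape[1]
    if ridge > 0:
        A_aug = np.vstack([A, np.sqrt(ridge) * D2])
        v_aug = np.concatenate([v, np.zeros(D2.shape[0])])
    else:
        A_aug, v_aug = A, v
    res = lsq_linear(A_aug, v_aug, bounds=(0.0, 1.0), method="bvls")
    if not res.success:
        raise RuntimeError(f"bounded least squares failed: {res.message}")
    return res.x


def infer_global(
    records: Sequence[tuple],
    knots: int = 12,
    ridge="cv",
    grid_size: int = 256,
    support_frac: float = 0.01,
) -> Landscape:
    """Fit one landscape to per-dose population invasiveness values.

    Each record pairs a seeded expression sample with its measured
    invasiveness.  A piecewise-linear w with ``knots`` interior knots over
    the pooled seeded support is fitted by bound-constrained least squares

        min_w  sum_d (E_seed,d[w] - v_d)^2 + ridge * ||D2 w||^2,   0 <= w <= 1,

    where ``E_seed,d[w]`` is the seeded-sample average of w at dose d and
    D2 the second-difference operator on the knot values.  With
    ``ridge='cv'`` the penalty weight is chosen by dose-blocked 5-fold
    cross-validation over a logarithmic grid.

    Parameters
    ----------
    records : sequence of (seeded sample, InvasivenessRecord) or (seeded, float)
    """
    if len(records) < 3:
        raise ValueError("infer_global needs at least 3 doses (underdetermined otherwise)")
    z_per_dose, v_per_dose = [], []
    for sample, rec in records:
        z_per_dose.append(_as_log10(sample))
        v_per_dose.append(float(getattr(rec, "v", rec)))
    v = np.asarray(v_per_dose)
    means = np.array([z.mean() for z in z_per_dose])
    if np.ptp(means) < 1e-9:
        raise ValueError("seeded samples must span distinct mean expression levels "
                         f"(observed mean spread {np.ptp(means):.2e} log10 a.u.)")
    pooled = np.concatenate(z_per_dose)
    lo, hi = np.percentile(pooled, [0.1, 99.9])
    nodes = np.linspace(lo, hi, knots + 2)          # interior knots + 2 boundary nodes
    A = np.vstack([_hat_basis(z, nodes).mean(axis=0) for z in z_per_dose])
    n_nodes = nodes.size
    D2 = np.zeros((n_nodes - 2, n_nodes))
    for i in range(n_nodes - 2):
        D2[i, i: i + 3] = (1.0, -2.0, 1.0)

    if ridge == "cv":
        ridge = _cv_ridge(A, v, D2)
    ridge = float(ridge)
    coef = _solve_bounded_ridge(A, v, D2, ridge)
    residuals = A @ coef - v

    grid = np.linspace(lo, hi, grid_size)
    w = np.interp(grid, nodes, coef)
    kde = stats.gaussian_kde(pooled)
    f_pooled = kde(grid)
    support = f_pooled >= support_frac * f_pooled.max()
    meta = {
        "estimator": "global",
        "knots": int(knots),
        "nodes": nodes.tolist(),
        "coef": coef.tolist(),
        "ridge": ridge,
        "residuals": residuals.tolist(),
        "rss": float(residuals @ residuals),
        "doses": [float(getattr(rec, "dose", np.nan)) for _, rec in records],
    }
    return Landscape(grid, w, support_mask=support, meta=meta)


def _cv_ridge(A, v, D2, grid=None, n_folds: int = 5) -> float:
    """Dose-blocked cross-validation for the second-difference penalty weight."""
    if grid is None:
        grid = np.logspace(-4, 0, 9)
    n = A.shape[0]
    n_folds = min(n_folds, n)
    folds = [np.arange(i, n, n_folds) for i in range(n_folds)]
    best, best_err = grid[0], np.inf
    for ridge in grid:
        err = 0.0
        for hold in folds:
            keep = np.setdiff1d(np.arange(n), hold)
            try:
                coef = _solve_bounded_ridge(A[keep], v[keep], D2, ridge)
            except RuntimeError:
                err = np.inf
                break
            err += float(np.sum((A[hold] @ coef - v[hold]) ** 2))
        if err < best_err:
            best, best_err = ridge, err
    return float(best)


def slope_sign_pattern(values, tol: float = 0.02) -> tuple[int, ...]:
    """Collapsed sign pattern of successive differences of knot values.

    Differences smaller than ``tol`` in absolute value are treated as
    flat and dropped; consecutive repeats are collapsed, so an
    up-down-up landscape yields (1, -1, 1) regardless of knot count.
    Useful for comparing the qualitative shape of a fitted landscape with
    a ground truth evaluated at the same knots.
    """
    diffs = np.diff(np.asarray(values, dtype=float))
    signs = [int(np.sign(d)) for d in diffs if abs(d) > tol]
    pattern: list[int] = []
    for s in signs:
        if not pattern or pattern[-1] != s:
            pattern.append(s)
    return tuple(pattern)


def expected_invasiveness(landscape: Landscape, seeded) -> float:
    """Analytic expectation of the Monte Carlo invasion assay.

    The mean of w over the seeded cells, i.e. the expected fraction of
    cells whose uniform draw falls below their landscape value.
    """
    z = _as_log10(seeded)
    return float(np.mean(landscape(z)))


def interpolate_2d(
    points: Sequence[tuple],
    mean_grid: np.ndarray | int = 50,
    cv_grid: np.ndarray | int = 50,
) -> Surface2D:
    """Biharmonic-spline invasiveness surface over (log10 mean, CV).

    Thin-plate-spline radial basis interpolation passing exactly through
    the input points; queries outside their convex hull are flagged as
    extrapolation.

    Parameters
    ----------
    points : sequence of (log10 mean, cv, invasiveness)
    """
    pts = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    vals = np.asarray([p[2] for p in points], dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points for a 2-D surface")
    # conflicting duplicates are an error; consistent ones are collapsed
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    if uniq.shape[0] < pts.shape[0]:
        for k in range(uniq.shape[0]):
            dup_vals = vals[inverse == k]
            if np.ptp(dup_vals) > 1e-12:
                raise ValueError(f"duplicate (mean, cv) point {tuple(uniq[k])} "
                                 "with conflicting invasiveness values")
        vals = np.array([vals[inverse == k][0] for k in range(uniq.shape[0])])
        pts = uniq
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("points are collinear; a 2-D surface is not identifiable")
    rbf = RBFInterpolator(pts, vals, kernel="thin_plate_spline", degree=1)
    try:
        hull = Delaunay(pts)
    except QhullError as exc:  # pragma: no cover - rank check above should catch
        raise ValueError("degenerate point configuration") from exc
    if np.isscalar(mean_grid):
        mean_grid = np.linspace(pts[:, 0].min(), pts[:, 0].max(), int(mean_grid))
    if np.isscalar(cv_grid):
        cv_grid = np.linspace(pts[:, 1].min(), pts[:, 1].max(), int(cv_grid))
    mg, cg = np.meshgrid(mean_grid, cv_grid)
    surface = rbf(np.column_stack([mg.ravel(), cg.ravel()])).reshape(mg.shape)
    return Surface2D(points=pts, values=vals, mean_grid=np.asarray(mean_grid),
                     cv_grid=np.asarray(cv_grid), surface=surface, _rbf=rbf, _hull=hull)


def local_geometry(
    landscape: Landscape,
    z0: float,
    window: float,
    flat_tol: float = 0.02,
) -> GeometryReport:
    """Classify the landscape locally as slope, peak, valley or flat.

    Fits a quadratic to w over [z0 - window, z0 + window] and compares the
    magnitudes of the slope and curvature contributions to the predicted
    change in w across the window.  Both below ``flat_tol`` (in w units)
    reads as flat; otherwise the dominant term decides: slope sign gives
    upslope/downslope, curvature sign gives valley (+) or peak (-).
    """
    z_lo, z_hi = z0 - window, z0 + window
    supported = landscape.z_grid[landscape.support_mask]
    if supported.size == 0 or z_lo < supported.min() - 1e-12 or z_hi > supported.max() + 1e-12:
        raise ValueError(f"window [{z_lo:.3g}, {z_hi:.3g}] extends outside the "
                         "supported region of the landscape")
    sel = (landscape.z_grid >= z_lo) & (landscape.z_grid <= z_hi)
    z = landscape.z_grid[sel] - z0
    w = landscape.w[sel]
    if z.size < 3:
        raise ValueError("window contains fewer than 3 grid points")
    c2, c1, _ = np.polyfit(z, w, 2)
    slope, curvature = float(c1), float(2 * c2)
    slope_effect = abs(slope) * window
    curv_effect = abs(curvature) * window**2 / 2.0
    if max(slope_effect, curv_effect) < flat_tol:
        kind = "flat"
    elif curv_effect > slope_effect:
        kind = "valley" if curvature > 0 else "peak"
    else:
        kind = "upslope" if slope > 0 else "downslope"
    return GeometryReport(kind=kind, slope=slope, curvature=curvature, z0=z0, window=window)
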