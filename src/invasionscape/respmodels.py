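"""Mechanistic response models: hemin degradation and iFFL dose responses.

Hemin accelerates degradation of the tuned protein.  With first-order
kinetics, production P and degradation rate delta0 + k_h * h, the steady
state is B = P / (delta0 + k_h h), so the fraction of protein remaining
relative to untreated cells,

    rho(h) = delta0 / (delta0 + k_h h),

is independent of the production rate — and hence of the inducer dose.
That lets a hemin dose be solved for any target ratio of mean levels
along a measured dose response (:func:`hemin_dose_for_target`).

An incoherent feedforward loop (iFFL) in which one regulator both
activates and represses a target through Hill links of different
sharpness produces nonmonotone (band-pass) responses when the two arms
have opposite effects; disabling either arm leaves a monotone response
(:class:`IFFLParams`, :func:`iffl_response`, :func:`find_extrema`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "HeminModel",
    "IFFLParams",
    "Extremum",
    "fraction_remaining",
    "hemin_dose_for_target",
    "iffl_response",
    "find_extrema",
]


@dataclass(frozen=True)
class HeminModel:
    """First-order degradation: basal rate delta0 (1/h) plus k_h * hemin."""

    delta0: float
    k_h: float

    def __post_init__(self) -> None:
        if self.delta0 <= 0:
            raise ValueError("delta0 must be positive")
        if self.k_h <= 0:
            raise ValueError("k_h must be positive")


def fraction_remaining(model: HeminModel, h: float) -> float:
    """Steady-state protein fraction remaining at hemin concentration h (µM).

    rho = delta0 / (delta0 + k_h h); production- (hence dox-) independent.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("hemin concentration must be non-negative")
    out = model.delta0 / (model.delta0 + model.k_h * h)
    return float(out) if out.ndim == 0 else out


def hemin_dose_for_target(model: HeminModel, mean_from: float, mean_to: float) -> float:
    """Hemin dose (µM) that scales mean level ``mean_from`` down to ``mean_to``.

    Solves rho = mean_to / mean_from for h = delta0 (1 - rho) / (k_h rho);
    exact round trip: fraction_remaining(h) == rho.  Hemin only degrades,
    so the target mean must not exceed the starting mean.
    """
    if mean_from <= 0 or mean_to < 0:
        raise ValueError("mean levels must be positive (target may be > 0)")
    rho = mean_to / mean_from
    if rho > 1.0:
        raise ValueError(f"target mean exceeds starting mean (ratio {rho:.3g} > 1); "
                         "hemin can only reduce levels")
    if rho == 0.0:
        raise ValueError("target mean of zero requires unbounded hemin")
    return float(model.delta0 * (1.0 - rho) / (model.k_h * rho))


@dataclass(frozen=True)
class IFFLParams:
    """Incoherent feedforward loop with Hill activation and repression arms.

    output(b) = basal + beta * act(b) * rep(b) with
    act(b) = b^n_act / (K_act^n_act + b^n_act) and
    rep(b) = K_rep^n_rep / (K_rep^n_rep + b^n_rep).  Setting
    ``activation=False`` (resp. ``repression=False``) replaces that arm by
    1, leaving a monotone single-link response.
    """

    beta: float = 1.0
    K_act: float = 1.0
    n_act: float = 4.0
    K_rep: float = 1.0
    n_rep: float = 1.0
    basal: float = 0.0
    activation: bool = True
    repression: bool = True

    def __post_init__(self) -> None:
        if self.K_act <= 0 or self.K_rep <= 0:
            raise ValueError("Hill thresholds must be positive")
        if self.n_act <= 0 or self.n_rep <= 0:
            raise ValueError("Hill coefficients must be positive")
        if self.beta < 0 or self.basal < 0:
            raise ValueError("beta and basal must be non-negative")


def iffl_response(params: IFFLParams, b) -> float | np.ndarray:
    """Target output at regulator level ``b`` (a.u.)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("regulator level must be non-negative")
    with np.errstate(divide="ignore"):
        bn_act = np.where(b > 0, b**params.n_act, 0.0)
        bn_rep = np.where(b > 0, b**params.n_rep, 0.0)
    act = bn_act / (params.K_act**params.n_act + bn_act) if params.activation else 1.0
    rep = (params.K_rep**params.n_rep / (params.K_rep**params.n_rep + bn_rep)
           if params.repression else 1.0)
    out = params.basal + params.beta * act * rep
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Extremum:
    b: float
    value: float
    kind: str  # 'max' or 'min'


def find_extrema(
    params: IFFLParams,
    b_range: tuple[float, float] = (0.0, 100.0),
    grid_n: int = 2000,
    prominence_frac: float = 0.01,
) -> tuple[list[Extremum], str]:
    """Interior extrema of the response over ``b_range`` and a verdict.

    Dense-grid sign changes of finite differences locate candidate
    extrema, refined by bounded golden-section search; extrema whose
    prominence is below ``prominence_frac`` of the output range are
    treated as numerical wiggles.  Verdict is 'nonmonotone' iff at least
    one interior extremum survives, else 'monotone'.
    """
    if grid_n < 100:
        raise ValueError("grid_n must be >= 100")
    lo, hi = float(b_range[0]), float(b_range[1])
    if hi <= lo:
        raise ValueError("empty b_range")
    # log-spaced grid (with b=0 kept if included) resolves sharp Hill arms
    if lo == 0.0:
        grid = np.concatenate([[0.0], np.geomspace(max(hi * 1e-6, 1e-12), hi, grid_n - 1)])
    else:
        grid = np.geomspace(lo, hi, grid_n)
    y = iffl_response(params, grid)
    out_range = float(np.ptp(y))
    tol = prominence_frac * out_range if out_range > 0 else np.inf
    dy = np.diff(y)
    sign = np.sign(dy)
    nz = np.flatnonzero(sign != 0)
    candidates: list[Extremum] = []
    for a, c in zip(nz[:-1], nz[1:]):
        if sign[a] == sign[c]:
            continue
        kind = "max" if sign[a] > 0 else "min"
        b_lo, b_hi = grid[max(a - 1, 0)], grid[min(c + 2, grid.size - 1)]
        direction = -1.0 if kind == "max" else 1.0
        res = minimize_scalar(lambda b: direction * iffl_response(params, b),
                              bounds=(b_lo, b_hi), method="bounded")
        b_star = float(res.x)
        candidates.append(Extremum(b=b_star, value=float(iffl_response(params, b_star)),
                                   kind=kind))
    # prominence of each candidate against its flanking reference levels
    # (the adjacent candidate extrema, or the range edges)
    anchors = ([y[0]] + [c.value for c in candidates] + [y[-1]])
    extrema = []
    for i, cand in enumerate(candidates):
        left, right = anchors[i], anchors[i + 2]
        prominence = (cand.value - max(left, right) if cand.kind == "max"
                      else min(left, right) - cand.value)
        if prominence >= tol:
            extrema.append(cand)
    verdict = "nonmonotone" if extrema else "monotone"
    return extrema, verdict
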