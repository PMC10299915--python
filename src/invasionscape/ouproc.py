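"""Exact Ornstein-Uhlenbeck dynamics for fluctuating log10 expression.

A cell's log10 expression level is modelled as a stationary OU process
with mean ``mu``, stationary SD ``sigma`` and relaxation time ``tau``
(hours).  The discrete update is the exact transition law

    x' = mu + (x - mu) e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) xi,

xi ~ N(0, 1), so moments are preserved for any step size — unlike an
Euler-Maruyama scheme, one step of 2*dt equals two steps of dt in
distribution.  Parameters come from moment matching to a log-transformed
sample (``fit_stationary``); tau is not identifiable from a single
snapshot and defaults to 24 h, commensurate with the 16-24 h assay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["OUParams", "fit_stationary", "simulate", "stationary_sample", "DEFAULT_TAU_H"]

#: Default relaxation time (hours) of log10 expression fluctuations.
DEFAULT_TAU_H = 24.0


@dataclass(frozen=True)
class OUParams:
    """Stationary mean/SD (log10 a.u.) and relaxation time (hours)."""

    mu: float
    sigma: float
    tau: float | None = DEFAULT_TAU_H

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")

    def with_tau(self, tau: float) -> "OUParams":
        return replace(self, tau=tau)


def fit_stationary(log_values) -> OUParams:
    """Moment-match mu and sigma to log10-transformed data; tau left unset."""
    z = np.asarray(log_values, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 values to fit stationary moments")
    sigma = float(z.std(ddof=0))
    if sigma == 0:
        raise ValueError("zero variance: stationary SD not identifiable")
    return OUParams(mu=float(z.mean()), sigma=sigma, tau=None)


def stationary_sample(params: OUParams, n: int, rng) -> np.ndarray:
    """Draw n levels from the stationary law N(mu, sigma^2)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.normal(params.mu, params.sigma, size=int(n))


def simulate(
    params: OUParams,
    x0,
    dt: float,
    n_steps: int,
    seed,
) -> np.ndarray:
    """Exact OU trajectories from initial levels ``x0``.

    Returns an array of shape (n_cells, n_steps + 1); column 0 is ``x0``
    and column j the state after j steps of size ``dt`` hours.  If
    x0 ~ N(mu, sigma^2), every column retains that stationary law.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if params.tau is None:
        raise ValueError("params.tau is unset; provide a relaxation time")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    decay = np.exp(-dt / params.tau)
    kick = params.sigma * np.sqrt(-np.expm1(-2.0 * dt / params.tau))
    traj = np.empty((x0.size, n_steps + 1))
    traj[:, 0] = x0
    x = x0.copy()
    for j in range(1, n_steps + 1):
        x = params.mu + (x - params.mu) * decay + kick * rng.standard_normal(x.size)
        traj[:, j] = x
    return traj
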