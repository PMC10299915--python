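"""Model/Results front end for invasion-landscape inference.

:class:`InvasionLandscapeModel` is built from data — either one
seeded/invaded sample pair with its measured invasiveness, or a dose
sweep of seeded samples with per-dose invasiveness — and ``fit()``
returns an :class:`InvasionLandscapeResults` carrying the estimated
landscape, its support, fit diagnostics, and methods to predict
invasiveness, simulate the assay, analyse selection and plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import invasionmc, selection as _selection
from .landscape import (
    GeometryReport,
    Landscape,
    expected_invasiveness,
    infer_global,
    infer_ratio,
    local_geometry,
)
from .ouproc import OUParams
from .synthgen import ExpressionSample

__all__ = ["InvasionLandscapeModel", "InvasionLandscapeResults"]


class InvasionLandscapeModel:
    """Invasion landscape w(z) to be estimated from assay data.

    Use :meth:`from_pair` for the single-condition ratio estimator or
    :meth:`from_dose_sweep` for the global piecewise-linear fit; the
    constructor accepts either input layout directly.
    """

    def __init__(self, seeded=None, invaded=None, v=None, sweep=None):
        if sweep is not None:
            if len(sweep) < 3:
                raise ValueError("a dose sweep needs at least 3 conditions")
            self.sweep = list(sweep)
            self.seeded = self.invaded = self.v = None
            self.kind = "sweep"
        else:
            if seeded is None or invaded is None or v is None:
                raise ValueError("provide (seeded, invaded, v) or a dose sweep")
            self.seeded, self.invaded, self.v = seeded, invaded, float(v)
            self.sweep = None
            self.kind = "pair"

    @classmethod
    def from_pair(cls, seeded, invaded, v: float) -> "InvasionLandscapeModel":
        """One condition: seeded sample, invaded sample, invasiveness v."""
        return cls(seeded=seeded, invaded=invaded, v=v)

    @classmethod
    def from_dose_sweep(cls, sweep: Sequence[tuple]) -> "InvasionLandscapeModel":
        """Dose sweep: (seeded sample, InvasivenessRecord or v) per dose."""
        return cls(sweep=sweep)

    def fit(self, **kwargs) -> "InvasionLandscapeResults":
        """Estimate the landscape.

        Keyword arguments are forwarded to :func:`infer_ratio`
        (bandwidth, support_frac, grid_size) or :func:`infer_global`
        (knots, ridge, grid_size, support_frac) depending on the input
        layout.
        """
        if self.kind == "pair":
            landscape = infer_ratio(self.seeded, self.invaded, self.v, **kwargs)
        else:
            landscape = infer_global(self.sweep, **kwargs)
        return InvasionLandscapeResults(model=self, landscape=landscape)


@dataclass
class InvasionLandscapeResults:
    """Fitted invasion landscape with diagnostics and downstream analyses."""

    model: InvasionLandscapeModel
    landscape: Landscape
    extras: dict = field(default_factory=dict)

    # -- predictions ---------------------------------------------------

    def predict(self, z) -> np.ndarray:
        """Invasion probability at log10 level(s) z."""
        return self.landscape(z)

    def expected_invasiveness(self, seeded) -> float:
        """Analytic population invasiveness for a seeded sample."""
        return expected_invasiveness(self.landscape, seeded)

    def simulate(self, cells, seed=0) -> invasionmc.InvasionResult:
        """Monte Carlo invasion assay on log10 levels (or a sample)."""
        z = cells.log10_values() if isinstance(cells, ExpressionSample) else cells
        return invasionmc.simulate_invasion(z, self.landscape, seed)

    def simulate_ou(self, params: OUParams, n_cells: int, assay_hours: float = 20.0,
                    **kwargs) -> invasionmc.InvasionResult:
        """Monte Carlo assay with OU-fluctuating levels during the window."""
        return invasionmc.simulate_invasion_ou(params, self.landscape, n_cells,
                                               assay_hours, **kwargs)

    def selection_report(self, seeded, **kwargs) -> _selection.SelectionReport:
        """Price-equation mean/variance shifts for a seeded population."""
        z = seeded.log10_values() if isinstance(seeded, ExpressionSample) else np.asarray(seeded)
        return _selection.price_shifts(z, self.landscape(z), **kwargs)

    def local_geometry(self, z0: float, window: float, **kwargs) -> GeometryReport:
        return local_geometry(self.landscape, z0, window, **kwargs)

    # -- diagnostics ---------------------------------------------------

    @property
    def residuals(self) -> np.ndarray | None:
        res = self.landscape.meta.get("residuals")
        return None if res is None else np.asarray(res)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        ls = self.landscape
        meta = ls.meta
        lines = ["Invasion landscape fit", "=" * 40]
        lines.append(f"estimator            {meta.get('estimator', '?')}")
        lines.append(f"grid                 {ls.z_grid.size} points on "
                     f"[{ls.z_grid[0]:.3f}, {ls.z_grid[-1]:.3f}] log10 a.u.")
        lines.append(f"support              {int(ls.support_mask.sum())}/{ls.z_grid.size} "
                     "grid points trusted")
        on = ls.w[ls.support_mask]
        lines.append(f"w range on support   [{on.min():.3f}, {on.max():.3f}]")
        if "bandwidth" in meta:
            lines.append(f"kde bandwidth        {meta['bandwidth']:.4f} log10 a.u.")
        if "v" in meta:
            lines.append(f"invasiveness input   {meta['v']:.4f}")
        if "knots" in meta:
            lines.append(f"knots                {meta['knots']} interior")
            lines.append(f"ridge                {meta['ridge']:.3g}")
            lines.append(f"rss                  {meta['rss']:.3g}")
            res = np.asarray(meta["residuals"])
            lines.append(f"max |residual|       {np.abs(res).max():.3g}")
        return "\n".join(lines)

    def plot(self, ax=None, show_support: bool = True):
        """Plot w(z); untrusted regions are dashed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ls = self.landscape
        ax.plot(ls.z_grid, ls.w, color="C0", lw=1.5, label="w(z)")
        if show_support and not ls.support_mask.all():
            masked = np.where(ls.support_mask, np.nan, ls.w)
            ax.plot(ls.z_grid, masked, color="C0", lw=1.5, ls="--", alpha=0.5,
                    label="outside support")
        ax.set_xlabel("log10 expression (a.u.)")
        ax.set_ylabel("invasion probability w")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(frameon=False)
        return ax
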