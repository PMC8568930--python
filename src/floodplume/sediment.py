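"""Suspended sediment: Rubey settling velocity, settling flux, deposition.

The fall speed of a mineral grain of diameter ``d`` and density
``rho_sed`` in water of density ``rho_w`` follows Rubey (1933), which
bridges the viscous (Stokes) and inertial regimes:

    w_s = F * sqrt(g * d * (s - 1)),          s = rho_sed / rho_w
    F   = sqrt(2/3 + 36 nu^2 / (g d^3 (s-1))) - sqrt(36 nu^2 / (g d^3 (s-1)))

For small d this reduces to Stokes' law g d^2 (s-1) / (18 nu); for large
d it tends to sqrt(2/3 * g d (s-1)).

Settling transport is a one-sided (downward) donor-cell flux; whatever
crosses the deepest wet face of a column is deposited permanently in a
:class:`DepositionLedger` — there is no resuspension, so deposition is
terminal and the ledger is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

__all__ = [
    "rubey_settling_velocity",
    "SedimentClass",
    "DepositionLedger",
    "apply_settling",
]


def rubey_settling_velocity(d: float, rho_sed: float = 2650.0,
                            rho_w: float = 1025.0, nu: float = 1.0e-6,
                            g: float = 9.81) -> float:
    """Rubey (1933) terminal fall velocity [m/s] of a grain of diameter d [m]."""
    if d <= 0:
        raise ValueError("particle diameter must be positive")
    if not (rho_sed > rho_w > 0):
        raise ValueError("need rho_sed > rho_w > 0")
    s = rho_sed / rho_w
    gd = g * d * (s - 1.0)
    visc = 36.0 * nu**2 / (g * d**3 * (s - 1.0))
    F = np.sqrt(2.0 / 3.0 + visc) - np.sqrt(visc)
    return float(F * np.sqrt(gd))


@dataclass(frozen=True)
class SedimentClass:
    """One grain-size class: diameter, grain density, derived fall speed."""

    d: float                    # particle diameter [m]
    rho_sed: float = 2650.0     # grain density [kg/m^3]
    nu: float = 1.0e-6          # kinematic viscosity used for w_s [m^2/s]
    rho_w: float = 1025.0       # carrier density used for w_s [kg/m^3]
    g: float = 9.81
    ws: float = field(init=False)   # settling speed [m/s]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "ws",
            rubey_settling_velocity(self.d, self.rho_sed, self.rho_w,
                                    self.nu, self.g))


@dataclass
class DepositionLedger:
    """Permanently deposited SSM mass, per column and in total.

    ``deposit`` is kg per m^2 of seafloor (per unit slice width divided by
    dx); ``total`` is the domain total per unit width [kg/m].
    """

    deposit: np.ndarray          # (nx,)
    total: float = 0.0

    @classmethod
    def empty(cls, grid: Grid) -> "DepositionLedger":
        return cls(deposit=np.zeros(grid.nx))

    def add_bottom_flux(self, flux_per_area: np.ndarray, grid: Grid) -> None:
        """Accumulate a bottom mass flux [kg/m^2] for this step."""
        self.deposit = self.deposit + flux_per_area
        self.total += float((flux_per_area * grid.dx).sum())


def apply_settling(C: np.ndarray, ws: float, grid: Grid, dt: float,
                   ledger: DepositionLedger | None = None,
                   bottom_sink=None) -> np.ndarray:
    """Settle concentration field ``C`` downward at speed ``ws`` for ``dt``.

    Donor-cell downward flux, sub-stepped so the settling Courant number
    never exceeds 1.  Mass crossing each column's deepest wet face goes to
    ``ledger`` (SSM) or, if ``bottom_sink`` is a callable, is handed to it
    (used to remineralise sinking detritus into bottom-cell nitrate).
    Column mass (water + deposit) is conserved to round-off.
    """
    if ws < 0:
        raise ValueError("settling speed must be non-negative")
    C = np.asarray(C, dtype=float).copy()
    if ws == 0.0 or dt == 0.0:
        return C
    dz = grid.dz
    nsub = max(1, int(np.ceil(ws * dt / dz.min())))
    dts = dt / nsub
    kb = grid.kbot - 1                      # deepest wet cell per column
    cols = np.arange(grid.nx)
    for _ in range(nsub):
        D = ws * C                                   # downward flux below each cell [kg/m^2/s]
        newC = C - dts * D / dz[:, None]
        recv = dts * D[:-1, :] / dz[1:, None]
        newC[1:, :] += np.where(grid.mask[1:, :], recv, 0.0)
        # mass leaving each column's deepest wet cell exits the water column
        bottom_out = dts * D[kb, cols]               # [kg/m^2]
        newC[~grid.mask] = 0.0
        C = newC
        if ledger is not None:
            ledger.add_bottom_flux(bottom_out, grid)
        elif bottom_sink is not None:
            bottom_sink(bottom_out)
    return C
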