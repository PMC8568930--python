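"""Nitrogen-based NPZD lower-trophic ecosystem.

Four pools in nitrogen currency [mol N/m^3]: nitrate N, phytoplankton P,
zooplankton Z and detritus D.  Source terms:

    uptake   = Vmax * exp(kT*T) * N/(N+Ks) * L(I) * P
    grazing  = Rmax * max(0, 1 - exp(-lambda*(P - P0))) * Z
    dP = uptake - grazing - mP*P
    dZ = gamma*grazing - mZ*Z^2
    dN = -uptake + rD*D
    dD = (1-gamma)*grazing + mP*P + mZ*Z^2 - rD*D

with the Steele photosynthesis–light curve L(I) = (I/Iopt)*exp(1-I/Iopt)
(photoinhibition above the optimum irradiance, default 65 W/m^2).  The
four tendencies sum to zero identically, so the nitrogen budget is closed
by construction; detritus sinking and its remineralisation into the
bottom cell are handled by the transport layer, not here.

Light decays with depth through background attenuation plus phytoplankton
self-shading.  Suspended sediment does not attenuate light in this model
(turbidity shading is a deliberate omission, documented in the methods
note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "BioParams",
    "steele_light_factor",
    "light_profile",
    "npzd_tendencies",
    "nitrogen_to_chla",
]


@dataclass(frozen=True)
class BioParams:
    """NPZD rate constants (rates per day, concentrations mol N/m^3)."""

    Vmax: float = 0.2            # max uptake at 0 degC [1/day]
    Ks: float = 1.0e-3           # N half-saturation [mol N/m^3] (1 umol/l)
    Iopt: float = 65.0           # optimum light [W/m^2]
    kT: float = 0.0693           # Eppley temperature coefficient [1/degC]
    kw: float = 0.15             # background light attenuation [1/m]
    kp: float = 60.0             # self-shading [1/m per mol N/m^3]
    Rmax: float = 0.3            # max grazing [1/day]
    lambda_ivlev: float = 1.4e3  # Ivlev constant [m^3/mol N]
    P0: float = 4.0e-5           # grazing threshold [mol N/m^3]
    mP: float = 0.05             # phytoplankton mortality [1/day]
    mZ: float = 2000.0           # zooplankton quadratic mortality [1/day/(mol N/m^3)]
    gamma: float = 0.7           # assimilation efficiency
    rD: float = 0.1              # detritus remineralisation [1/day]
    wD: float = 1.16e-4          # detritus sinking speed [m/s] (~10 m/day)
    chl_per_N: float = 1.59      # ug chl.a per umol N (Redfield C:N 6.625, C:chl 50)

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.Iopt <= 0:
            raise ValueError("Iopt must be positive")
        for name in ("Vmax", "Ks", "kw", "kp", "Rmax", "lambda_ivlev",
                     "P0", "mP", "mZ", "rD", "wD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def steele_light_factor(I, Iopt: float):
    """Steele photosynthesis-light response (I/Iopt)*exp(1 - I/Iopt) in [0, 1]."""
    x = np.asarray(I, dtype=float) / Iopt
    return x * np.exp(1.0 - x)


def light_profile(I_surface, P, grid: Grid, params: BioParams) -> np.ndarray:
    """Irradiance at cell centres, attenuated by water and self-shading.

    I(z) = I_surface * exp(-integral_0^z (kw + kp*P) dz'), with P treated
    as piecewise constant per layer (the integral to a cell centre is the
    sum over full layers above plus half the cell's own layer).
    """
    if np.any(np.asarray(I_surface) < 0):
        raise ValueError("surface irradiance must be non-negative")
    P = np.asarray(P, dtype=float)
    dz = grid.dz[:, None]
    layer_od = (params.kw + params.kp * P) * dz          # optical depth per layer
    above = np.cumsum(layer_od, axis=0) - layer_od       # full layers above
    tau = above + 0.5 * layer_od
    I = np.asarray(I_surface, dtype=float) * np.exp(-tau)
    return np.where(grid.mask, I, 0.0)


def npzd_tendencies(N, P, Z, D, T, I, params: BioParams):
    """Source terms (dN, dP, dZ, dD) in mol N/m^3 per day.

    Inputs may be scalars or arrays; all pools must be non-negative.
    The four returned tendencies sum to zero exactly.
    """
    N, P, Z, D = (np.asarray(a, dtype=float) for a in (N, P, Z, D))
    if min(N.min(initial=0), P.min(initial=0), Z.min(initial=0), D.min(initial=0)) < 0:
        raise ValueError("NPZD state must be non-negative")
    uptake = (params.Vmax * np.exp(params.kT * np.asarray(T, float))
              * N / (N + params.Ks)
              * steele_light_factor(I, params.Iopt) * P)
    grazing = params.Rmax * np.maximum(
        0.0, 1.0 - np.exp(-params.lambda_ivlev * (P - params.P0))) * Z
    mortP = params.mP * P
    mortZ = params.mZ * Z * Z
    remin = params.rD * D
    dP = uptake - grazing - mortP
    dZ = params.gamma * grazing - mortZ
    dN = -uptake + remin
    dD = (1.0 - params.gamma) * grazing + mortP + mortZ - remin
    return dN, dP, dZ, dD


def nitrogen_to_chla(P, chl_per_N: float = 1.59):
    """Convert phytoplankton nitrogen [umol N/l] to chlorophyll-a [ug/l]."""
    return np.asarray(P, dtype=float) * chl_per_N
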