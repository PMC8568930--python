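"""Physical parameters and the sediment-aware equation of state.

Bulk density of a water–sediment suspension is the volume-weighted mix of
seawater and mineral grains,

    rho = rho_w(T, S) + (1 - rho_w / rho_sed) * C,

where ``C`` is the suspended sediment concentration [kg/m^3] and
``rho_w`` is a linear seawater equation of state

    rho_w = rho0 * (1 - alpha*(T - T0) + beta*(S - S0)).

The SSM term is what couples sediment load to plume dynamics: it is
strictly increasing in ``C`` with slope ``(1 - rho_w/rho_sed)`` between 0
and 1, and it makes a sufficiently sediment-laden freshwater discharge
denser than ambient seawater (the hyperpycnal threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysParams",
    "water_density",
    "equation_of_state",
    "ssm_density_crossing",
]


@dataclass(frozen=True)
class PhysParams:
    """Reference-state and closure constants of the dynamical core.

    All units SI.  ``f = 0`` disables rotation (pure 2-D slice); a nonzero
    Coriolis parameter activates the transverse-velocity equation
    (2.5-D mode).
    """

    rho0: float = 1025.0        # reference seawater density [kg/m^3]
    alpha: float = 2.0e-4       # thermal expansion [1/degC]
    beta: float = 7.8e-4        # haline contraction [1/psu]
    T0: float = 20.0            # reference temperature [degC]
    S0: float = 33.0            # reference salinity [psu]
    rho_sed: float = 2650.0     # sediment grain density [kg/m^3]
    nu: float = 1.0e-6          # molecular kinematic viscosity [m^2/s]
    g: float = 9.81             # gravity [m/s^2]
    Ah: float = 5.0             # horizontal eddy viscosity [m^2/s]
    Av: float = 1.0e-3          # vertical eddy viscosity [m^2/s]
    Kh: float = 5.0             # horizontal eddy diffusivity [m^2/s]
    Kv: float = 5.0e-5          # vertical eddy diffusivity [m^2/s]
    f: float = 0.0              # Coriolis parameter [1/s]
    Cd_bot: float = 2.5e-3      # quadratic bottom drag coefficient

    def __post_init__(self) -> None:
        if not (self.rho_sed > self.rho0 > 0):
            raise ValueError("need rho_sed > rho0 > 0")
        if min(self.nu, self.g, self.Ah, self.Av, self.Kh, self.Kv) <= 0:
            raise ValueError("viscosities, diffusivities, nu and g must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


def water_density(T, S, params: PhysParams):
    """Linear seawater density rho_w(T, S) [kg/m^3] (no sediment)."""
    return params.rho0 * (1.0 - params.alpha * (np.asarray(T) - params.T0)
                          + params.beta * (np.asarray(S) - params.S0))


def equation_of_state(T, S, C, params: PhysParams, *, validate: bool = True):
    """Bulk density of the sediment-laden suspension [kg/m^3].

    Raises ``ValueError`` for negative sediment concentration or
    non-finite inputs.  ``validate=False`` skips the checks in the model's
    inner loop (the stepper validates state separately).
    """
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    if validate:
        if np.any(C < 0):
            raise ValueError("SSM concentration must be non-negative")
        for a in (T, S, C):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite input to equation of state")
    rho_w = water_density(T, S, params)
    return rho_w + (1.0 - rho_w / params.rho_sed) * C


def ssm_density_crossing(params: PhysParams, T_river: float,
                         T_ambient: float, S_ambient: float) -> float:
    """SSM concentration C* at which river water matches ambient density.

    Closed-form rearrangement of the equation of state: river water
    (S = 0, temperature ``T_river``) carrying ``C*`` kg/m^3 of sediment has
    exactly the density of ambient seawater ``(T_ambient, S_ambient)``:

        C* = (rho_w(T_amb, S_amb) - rho_w(T_riv, 0))
             / (1 - rho_w(T_riv, 0) / rho_sed).
    """
    rho_amb = float(water_density(T_ambient, S_ambient, params))
    rho_riv = float(water_density(T_river, 0.0, params))
    return (rho_amb - rho_riv) / (1.0 - rho_riv / params.rho_sed)
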