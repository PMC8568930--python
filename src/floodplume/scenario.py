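"""Synthetic forcing: flood hydrograph, river inputs, initial ocean, case grid.

Everything the simulation consumes is generated here from configuration —
no external data.  The generator emulates the structural features the
analysis assumes: one dominant river discharging into a salt-stratified
microtidal bay, a single flood pulse lasting about a day on top of a
62.46 m^3/s base flow, a nutrient-depleted surface layer over a
nutrient-rich sub-surface with a sub-surface chlorophyll maximum, and a
sensitivity grid of (SSM amount, particle diameter, riverine nutrient)
multipliers around a standard case (STD), with a no-sediment reference
(WOS) per nutrient level.

The STD sediment load follows a rating curve C_STD(Q) = a * Q^b.  Its
magnitude is a calibration, not an observation: ``StdInputs.calibrated``
fixes ``a`` so that the predicted river–sea density difference at the
flood peak crosses zero at five times the STD load, placing the
hypopycnal→hyperpycnal transition between multipliers 4 and 6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .physics import PhysParams, equation_of_state, ssm_density_crossing

__all__ = [
    "FloodPulse",
    "Hydrograph",
    "StdInputs",
    "CaseSpec",
    "InitialOceanParams",
    "InitialOcean",
    "synthetic_flood_hydrograph",
    "riverine_concentrations",
    "build_initial_ocean",
    "case_grid",
    "hypopycnal_preset",
    "hyperpycnal_preset",
    "BASE_DISCHARGE",
    "STD_NUTRIENT",
]

BASE_DISCHARGE = 62.46     # annual-mean river discharge [m^3/s]
STD_NUTRIENT = 0.046       # standard-case riverine nitrate [mol N/m^3]


@dataclass(frozen=True)
class FloodPulse:
    """Closed-form single-peak hydrograph shape.

    Discharge is exactly ``base_Q`` outside the compact pulse window
    [t_peak - rise, t_peak + fall]; inside it follows a C^1 raised-cosine
    ramp up and down, peaking at exactly ``peak_Q`` at ``t_peak``.
    """

    base_Q: float
    peak_Q: float
    t_peak: float      # [s]
    rise: float        # [s]
    fall: float        # [s]
    duration: float    # run window [s]

    def __post_init__(self) -> None:
        if self.peak_Q < self.base_Q:
            raise ValueError("peak_Q must be >= base_Q")
        if self.rise <= 0 or self.fall <= 0 or self.duration <= 0:
            raise ValueError("rise, fall and duration must be positive")
        if not (0.0 <= self.t_peak <= self.duration):
            raise ValueError("t_peak must lie inside the run window")

    def discharge(self, t):
        t = np.asarray(t, dtype=float)
        s = np.where(t < self.t_peak,
                     (t - self.t_peak) / self.rise,
                     (t - self.t_peak) / self.fall)
        bump = np.where(np.abs(s) < 1.0, 0.5 * (1.0 + np.cos(np.pi * s)), 0.0)
        return self.base_Q + (self.peak_Q - self.base_Q) * bump

    def flood_volume(self) -> float:
        """Exact integral of Q - base_Q over the pulse [m^3]."""
        return (self.peak_Q - self.base_Q) * 0.5 * (self.rise + self.fall)


@dataclass(frozen=True)
class Hydrograph:
    """Sampled river time series: discharge plus boundary concentrations."""

    times: np.ndarray      # [s]
    Q: np.ndarray          # [m^3/s]
    Criver: np.ndarray     # SSM at the river mouth [kg/m^3]
    Nriver: np.ndarray     # nitrate at the river mouth [mol N/m^3]
    pulse: FloodPulse | None = None

    def __post_init__(self) -> None:
        if np.any(self.Q < 0) or np.any(self.Criver < 0) or np.any(self.Nriver < 0):
            raise ValueError("hydrograph series must be non-negative")


@dataclass(frozen=True)
class StdInputs:
    """Standard-case river inputs: nutrient level and SSM rating curve."""

    nutrient_conc: float = STD_NUTRIENT   # [mol N/m^3]
    rating_a: float = 2.5e-3              # C_STD = a * Q^b  [kg/m^3 per (m^3/s)^b]
    rating_b: float = 1.3

    def c_std(self, Q):
        return self.rating_a * np.asarray(Q, dtype=float) ** self.rating_b

    @classmethod
    def calibrated(cls, phys: PhysParams, *, T_river: float, T_ambient: float,
                   S_ambient: float, peak_Q: float, crossing_mult: float = 5.0,
                   rating_b: float = 1.3,
                   nutrient_conc: float = STD_NUTRIENT) -> "StdInputs":
        """Pin the rating curve so crossing_mult x STD is density-neutral at peak flow."""
        c_star = ssm_density_crossing(phys, T_river, T_ambient, S_ambient)
        a = (c_star / crossing_mult) / peak_Q ** rating_b
        return cls(nutrient_conc=nutrient_conc, rating_a=a, rating_b=rating_b)


@dataclass(frozen=True)
class CaseSpec:
    """One sensitivity-grid cell.

    ``ssm_mult`` scales the STD sediment load (0 = the WOS reference, in
    which case ``diameter`` is irrelevant and may be None); ``diameter``
    is the grain size [m]; ``nutrient_mult`` scales the STD riverine
    nutrient concentration.
    """

    ssm_mult: float
    diameter: float | None
    nutrient_mult: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.ssm_mult <= 10.0):
            raise ValueError("ssm_mult must be within [0, 10]")
        if not (0.0 <= self.nutrient_mult <= 10.0):
            raise ValueError("nutrient_mult must be within [0, 10]")
        if self.ssm_mult > 0 and (self.diameter is None or self.diameter <= 0):
            raise ValueError("SSM-bearing cases need a positive diameter")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    @property
    def is_wos(self) -> bool:
        return self.ssm_mult == 0.0

    def default_label(self) -> str:
        if self.is_wos:
            return f"WOS_n{self.nutrient_mult:g}"
        return (f"ssm{self.ssm_mult:g}_d{self.diameter * 1e3:g}mm"
                f"_n{self.nutrient_mult:g}")


def synthetic_flood_hydrograph(base_Q: float, peak_Q: float, t_peak: float,
                               rise: float, fall: float, duration: float,
                               cadence: float = 3600.0,
                               case: CaseSpec | None = None,
                               std: StdInputs | None = None) -> Hydrograph:
    """Sample the closed-form flood pulse onto a regular time grid.

    The sample grid always contains ``t_peak`` so the series maximum is
    exactly ``peak_Q``.  If a case and STD inputs are given, river
    concentrations are filled via :func:`riverine_concentrations`,
    otherwise they are zero.
    """
    pulse = FloodPulse(base_Q, peak_Q, t_peak, rise, fall, duration)
    times = np.unique(np.concatenate([
        np.arange(0.0, duration + 0.5 * cadence, cadence), [t_peak]]))
    Q = pulse.discharge(times)
    if case is not None and std is not None:
        C, N = riverine_concentrations(Q, case, std)
    else:
        C, N = np.zeros_like(Q), np.zeros_like(Q)
    return Hydrograph(times=times, Q=Q, Criver=C, Nriver=N, pulse=pulse)


def riverine_concentrations(Q, case: CaseSpec, std: StdInputs):
    """River-mouth SSM and nutrient concentrations for one case.

    Nriver = STD nutrient x nutrient multiplier (discharge-independent);
    Criver = ssm multiplier x rating curve a*Q^b.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q <= 0):
        raise ValueError("discharge must be positive")
    C = case.ssm_mult * std.c_std(Q)
    N = std.nutrient_conc * case.nutrient_mult * np.ones_like(Q)
    if C.ndim == 0:
        return float(C), float(N)
    return C, N


@dataclass(frozen=True)
class InitialOceanParams:
    """Shape parameters of the pre-flood stratified bay."""

    T_surface: float = 24.0      # [degC]
    T_deep: float = 16.0
    thermocline_depth: float = 12.0   # [m]
    thermocline_width: float = 6.0
    S_surface: float = 32.0      # [psu]
    S_deep: float = 33.8
    halocline_depth: float = 8.0
    halocline_width: float = 4.0
    N_surface: float = 5.0e-4    # depleted surface nitrate [mol N/m^3]
    N_deep: float = 4.0e-3       # nutrient-rich sub-surface
    nutricline_depth: float = 10.0
    nutricline_width: float = 5.0
    P_background: float = 2.0e-4  # [mol N/m^3]
    P_scm: float = 8.0e-4         # sub-surface chlorophyll maximum amplitude
    scm_depth: float = 10.0       # [m]
    scm_width: float = 4.0
    Z_frac: float = 0.1           # Z = Z_frac * P
    D_background: float = 1.0e-4


@dataclass(frozen=True)
class InitialOcean:
    """Horizontally uniform initial profiles on the model layers."""

    grid: Grid
    T: np.ndarray
    S: np.ndarray
    N: np.ndarray
    P: np.ndarray
    Z: np.ndarray
    D: np.ndarray

    def density(self, phys: PhysParams) -> np.ndarray:
        return equation_of_state(self.T, self.S, np.zeros_like(self.S), phys)


def build_initial_ocean(grid: Grid, prm: InitialOceanParams,
                        phys: PhysParams | None = None) -> InitialOcean:
    """Stably stratified profiles with a sub-surface chlorophyll maximum.

    Temperature and salinity follow tanh ramps across the thermocline and
    halocline; nitrate is depleted above the nutricline; phytoplankton is
    a background plus a Gaussian sub-surface maximum.  Raises if the
    requested profile is statically unstable.
    """
    if phys is None:
        phys = PhysParams()
    z = grid.z_c

    def ramp(top, bottom, depth, width):
        return top + (bottom - top) * 0.5 * (
            1.0 + np.tanh((z - depth) / max(width, 1e-6)))

    T = ramp(prm.T_surface, prm.T_deep, prm.thermocline_depth, prm.thermocline_width)
    S = ramp(prm.S_surface, prm.S_deep, prm.halocline_depth, prm.halocline_width)
    N = ramp(prm.N_surface, prm.N_deep, prm.nutricline_depth, prm.nutricline_width)
    P = prm.P_background + prm.P_scm * np.exp(
        -0.5 * ((z - prm.scm_depth) / prm.scm_width) ** 2)
    Z = prm.Z_frac * P
    D = np.full_like(z, prm.D_background)

    rho = equation_of_state(T, S, np.zeros_like(S), phys)
    if np.any(np.diff(rho) < -1e-12):
        raise ValueError("requested initial profile is statically unstable")
    if prm.N_surface > prm.N_deep:
        raise ValueError("surface nitrate must not exceed sub-surface nitrate")
    return InitialOcean(grid=grid, T=T, S=S, N=N, P=P, Z=Z, D=D)


def case_grid(ssm_mults, diameters, nutrient_mults) -> list[CaseSpec]:
    """Cartesian sensitivity grid plus one WOS reference per nutrient level.

    Multiplier zero in ``ssm_mults`` is folded into the WOS references
    (the no-sediment case does not depend on the diameter).  Duplicates
    are removed; cases are ordered WOS-first, then lexicographically.
    """
    ssm = sorted({float(m) for m in ssm_mults})
    dia = sorted({float(d) for d in diameters})
    nut = sorted({float(n) for n in nutrient_mults}) or [1.0]
    for m in ssm:
        if not 0.0 <= m <= 10.0:
            raise ValueError(f"ssm multiplier {m} outside [0, 10]")
    for n in nut:
        if not 0.0 <= n <= 10.0:
            raise ValueError(f"nutrient multiplier {n} outside [0, 10]")
    cases: list[CaseSpec] = [CaseSpec(0.0, None, n) for n in nut]
    for m, d, n in itertools.product(ssm, dia, nut):
        if m == 0.0:
            continue
        cases.append(CaseSpec(m, d, n))
    return cases


def hypopycnal_preset(nutrient_mult: float = 1.0) -> CaseSpec:
    """Typical hypopycnal case: SSM 4x STD, diameter 0.05 mm."""
    return CaseSpec(4.0, 5.0e-5, nutrient_mult, label="hypopycnal")


def hyperpycnal_preset(nutrient_mult: float = 1.0) -> CaseSpec:
    """Typical hyperpycnal case: SSM 10x STD, diameter 0.01 mm."""
    return CaseSpec(10.0, 1.0e-5, nutrient_mult, label="hyperpycnal")
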