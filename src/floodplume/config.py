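"""Run configuration: schema-validated, hashable, YAML round-trip.

A :class:`RunConfig` pins every knob of a simulation campaign — grid,
physics, sediment, biology, scenario, diagnostics, output cadence and the
seed — so that one config plus the code version fixes every output byte.
Unknown keys are rejected (``extra='forbid'``), which catches typos
before a multi-case sweep burns CPU time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .grid import Grid
from .physics import PhysParams
from .ecosystem import BioParams
from .scenario import (InitialOceanParams, StdInputs, FloodPulse,
                       BASE_DISCHARGE, STD_NUTRIENT)

__all__ = ["RunConfig", "default_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Section):
    nx: int = 64
    dx: float = 250.0
    dz: list[float] = [1.0, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 7.0]
    h_inshore: float = 10.0
    h_offshore: float = 40.0

    def build(self) -> Grid:
        return Grid.sloping(self.nx, self.dx, np.array(self.dz),
                            self.h_inshore, self.h_offshore)


class PhysicsSection(_Section):
    rho0: float = 1025.0
    alpha: float = 2.0e-4
    beta: float = 7.8e-4
    T0: float = 20.0
    S0: float = 33.0
    rho_sed: float = 2650.0
    nu: float = 1.0e-6
    g: float = 9.81
    Ah: float = 5.0
    Av: float = 1.0e-3
    Kh: float = 5.0
    Kv: float = 5.0e-5
    f: float = 0.0
    Cd_bot: float = 2.5e-3

    def build(self) -> PhysParams:
        return PhysParams(**self.model_dump())


class SedimentSection(_Section):
    rho_sed: float = 2650.0
    nu: float = 1.0e-6
    rho_w: float = 1025.0


class BiologySection(_Section):
    Vmax: float = 0.2
    Ks: float = 1.0e-3
    Iopt: float = 65.0
    kT: float = 0.0693
    kw: float = 0.15
    kp: float = 60.0
    Rmax: float = 0.3
    lambda_ivlev: float = 1.4e3
    P0: float = 4.0e-5
    mP: float = 0.05
    mZ: float = 2000.0
    gamma: float = 0.7
    rD: float = 0.1
    wD: float = 1.16e-4
    chl_per_N: float = 1.59

    def build(self) -> BioParams:
        return BioParams(**self.model_dump())


class ScenarioSection(_Section):
    base_Q: float = BASE_DISCHARGE
    peak_Q: float = 3000.0
    t_peak_h: float = 24.0
    rise_h: float = 10.0
    fall_h: float = 14.0
    duration_h: float = 120.0
    river_width: float = 30000.0
    river_layers: int = 2
    T_river: float = 20.0
    I_surface: float = 80.0
    nutrient_std: float = STD_NUTRIENT
    rating_b: float = 1.3
    crossing_mult: float = 5.0
    spinup_days: float = 3.0
    sponge_cols: int = 8
    sponge_rate: float = 1.0 / 1800.0
    initial: InitialOceanSection | None = None

    def pulse(self) -> FloodPulse:
        return FloodPulse(self.base_Q, self.peak_Q, self.t_peak_h * 3600.0,
                          self.rise_h * 3600.0, self.fall_h * 3600.0,
                          self.duration_h * 3600.0)


class InitialOceanSection(_Section):
    T_surface: float = 24.0
    T_deep: float = 16.0
    thermocline_depth: float = 12.0
    thermocline_width: float = 6.0
    S_surface: float = 32.0
    S_deep: float = 33.8
    halocline_depth: float = 8.0
    halocline_width: float = 4.0
    N_surface: float = 5.0e-4
    N_deep: float = 4.0e-3
    nutricline_depth: float = 10.0
    nutricline_width: float = 5.0
    P_background: float = 2.0e-4
    P_scm: float = 8.0e-4
    scm_depth: float = 10.0
    scm_width: float = 4.0
    Z_frac: float = 0.1
    D_background: float = 1.0e-4

    def build(self) -> InitialOceanParams:
        return InitialOceanParams(**self.model_dump())


class DiagnosticsSection(_Section):
    salinity_threshold: float = 28.0
    surface_layers: int = 2
    mask_source: str = "reference"
    neutral_tol: float = 0.01


class OutputSection(_Section):
    cadence_h: float = 1.0
    outdir: str = "results/runs"
    save_fields: bool = False


class RunConfig(_Section):
    grid: GridSection = GridSection()
    physics: PhysicsSection = PhysicsSection()
    sediment: SedimentSection = SedimentSection()
    biology: BiologySection = BiologySection()
    scenario: ScenarioSection = ScenarioSection()
    diagnostics: DiagnosticsSection = DiagnosticsSection()
    output: OutputSection = OutputSection()
    seed: int = 0

    # -- persistence --------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def std_inputs(self) -> StdInputs:
        init = (self.scenario.initial or InitialOceanSection()).build()
        return StdInputs.calibrated(
            self.physics.build(),
            T_river=self.scenario.T_river,
            T_ambient=init.T_surface,
            S_ambient=init.S_surface,
            peak_Q=self.scenario.peak_Q,
            crossing_mult=self.scenario.crossing_mult,
            rating_b=self.scenario.rating_b,
            nutrient_conc=self.scenario.nutrient_std)


ScenarioSection.model_rebuild()


def default_config(seed: int = 0, **overrides) -> RunConfig:
    cfg = RunConfig(seed=seed)
    if overrides:
        data = cfg.model_dump()
        for key, val in overrides.items():
            sec, _, name = key.partition(".")
            if name:
                data[sec][name] = val
            else:
                data[sec] = val
        cfg = RunConfig.model_validate(data)
    return cfg
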