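"""Shared fixtures: small grids, a cheap end-to-end config, and the
session-scoped sensitivity sweep the acceptance tests read from."""

from __future__ import annotations

import numpy as np
import pytest

from floodplume.config import default_config
from floodplume.grid import Grid
from floodplume.physics import PhysParams
from floodplume.ecosystem import BioParams
from floodplume.pipeline import (build_plume_params, extended_sweep_cases,
                                 run_case, run_sweep)
from floodplume.scenario import (CaseSpec, InitialOceanParams,
                                 build_initial_ocean, hyperpycnal_preset,
                                 hypopycnal_preset)


@pytest.fixture()
def phys() -> PhysParams:
    return PhysParams()


@pytest.fixture()
def bio() -> BioParams:
    return BioParams()


@pytest.fixture()
def grid_small() -> Grid:
    """Tiny flat-bottom grid for transport/adjustment unit tests."""
    return Grid.uniform(nx=12, dx=100.0, dz=np.array([1.0, 1.0, 1.5, 2.0, 2.5]))


@pytest.fixture()
def initial_small(grid_small, phys):
    return build_initial_ocean(grid_small, InitialOceanParams(), phys)


@pytest.fixture()
def tiny_config():
    """A minutes-long end-to-end configuration for pipeline tests."""
    return default_config(**{
        "grid.nx": 32,
        "scenario.t_peak_h": 3.0,
        "scenario.rise_h": 1.5,
        "scenario.fall_h": 2.0,
        "scenario.duration_h": 8.0,
        "scenario.spinup_days": 0.05,
        "scenario.sponge_cols": 4,
        "scenario.river_width": 3000.0,   # narrow slice: plume forms fast
    })


def _case_key(c: CaseSpec):
    return (c.ssm_mult, c.diameter, c.nutrient_mult)


class SweepHandle:
    """Accessors over the session sweep for the analysis-level tests."""

    def __init__(self, cfg, result):
        self.cfg = cfg
        self.result = result
        self.pp = build_plume_params(cfg)
        self._by_key = {_case_key(c): c.label for c in result.cases}

    def series(self, ssm_mult, diameter, nutrient_mult=1.0):
        key = (float(ssm_mult),
               None if ssm_mult == 0 else float(diameter),
               float(nutrient_mult))
        return self.result.series[self._by_key[key]]

    @property
    def hypopycnal(self):
        c = hypopycnal_preset()
        return self.series(c.ssm_mult, c.diameter, c.nutrient_mult)

    @property
    def hyperpycnal(self):
        c = hyperpycnal_preset()
        return self.series(c.ssm_mult, c.diameter, c.nutrient_mult)

    @property
    def t_peak(self) -> float:
        return self.cfg.scenario.t_peak_h * 3600.0


@pytest.fixture(scope="session")
def sweep() -> SweepHandle:
    """The full default-configuration sensitivity sweep (run once).

    Covers SSM multipliers {0,1,2,4,6,8,10} x diameters {10,20,50} um x
    nutrient multipliers {0.1,1,10}; the two typical-regime presets are
    cells of this grid.
    """
    cfg = default_config()
    result = run_sweep(cfg, extended_sweep_cases(), outdir=None)
    return SweepHandle(cfg, result)


def sweep_run(handle: SweepHandle, ssm_mult, diameter, nutrient_mult=1.0):
    """Raw CaseRun (with budget report) for one sweep cell."""
    key = (float(ssm_mult),
           None if ssm_mult == 0 else float(diameter),
           float(nutrient_mult))
    return handle.result.runs[handle._by_key[key]]
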