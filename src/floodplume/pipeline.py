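"""Campaign orchestration: spinup, single cases, sensitivity sweeps.

A case run is deterministic given (config, case): the spinup state is
computed once per nutrient multiplier and shared (the spinup carries no
sediment; at base flow the SSM load is negligible and the no-sediment
reference must share the case's starting point bitwise), then the flood
window is integrated with hourly surface diagnostics recorded.  Sweeps
cache the WOS reference per nutrient level, write per-case plume-series
CSVs and a JSON manifest, and can resume: completed cases found in the
manifest are loaded from their CSVs instead of recomputed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _code_version
from .config import RunConfig
from .diagnostics import (PlumeParams, PlumeSeries, SurfaceSeries,
                          build_regime_map, difference_series,
                          river_density_difference)
from .model import OceanState, PlumeModel, RiverForcing, SpongeConfig
from .scenario import CaseSpec, build_initial_ocean, case_grid
from .sediment import SedimentClass

__all__ = [
    "build_plume_params", "spinup", "run_case", "run_sweep",
    "SweepResult", "default_sweep_cases", "extended_sweep_cases",
]


def build_plume_params(cfg: RunConfig) -> PlumeParams:
    d = cfg.diagnostics
    return PlumeParams(salinity_threshold=d.salinity_threshold,
                       surface_layers=d.surface_layers,
                       mask_source=d.mask_source,
                       neutral_tol=d.neutral_tol)


def _components(cfg: RunConfig):
    grid = cfg.grid.build()
    phys = cfg.physics.build()
    bio = cfg.biology.build()
    from .config import InitialOceanSection
    init_prm = (cfg.scenario.initial or InitialOceanSection()).build()
    initial = build_initial_ocean(grid, init_prm, phys)
    std = cfg.std_inputs()
    pulse = cfg.scenario.pulse()
    sponge = SpongeConfig(n_cols=cfg.scenario.sponge_cols,
                          rate=cfg.scenario.sponge_rate)
    return grid, phys, bio, initial, std, pulse, sponge


def _make_model(cfg: RunConfig, case: CaseSpec, comps) -> PlumeModel:
    grid, phys, bio, initial, std, pulse, sponge = comps
    sed = None
    if case.diameter is not None:
        sed = SedimentClass(d=case.diameter, rho_sed=cfg.sediment.rho_sed,
                            nu=cfg.sediment.nu, rho_w=cfg.sediment.rho_w,
                            g=phys.g)
    forcing = RiverForcing(pulse=pulse, case=case, std=std,
                           width=cfg.scenario.river_width,
                           n_layers=cfg.scenario.river_layers,
                           T_river=cfg.scenario.T_river,
                           I_surface=cfg.scenario.I_surface)
    return PlumeModel(grid, phys, bio, sediment=sed, forcing=forcing,
                      sponge=sponge, initial=initial)


def spinup(cfg: RunConfig, nutrient_mult: float = 1.0,
           days: float | None = None, _cache: dict = {}) -> OceanState:
    """Quasi-steady pre-flood state under constant base flow (cached).

    The river runs at base discharge with the case's nutrient level and
    no sediment; the state returned is shared by every case with the same
    nutrient multiplier, which keeps the WOS comparison clean.
    """
    if days is None:
        days = cfg.scenario.spinup_days
    key = (cfg.hash(), float(nutrient_mult), float(days))
    if key in _cache:
        return _cache[key].copy()
    comps = _components(cfg)
    grid, phys, bio, initial, std, pulse, sponge = comps
    from .scenario import FloodPulse
    flat = FloodPulse(pulse.base_Q, pulse.base_Q, 0.0, 3600.0, 3600.0,
                      max(days * 86400.0, 3600.0))
    case = CaseSpec(0.0, None, nutrient_mult, label=f"spinup_n{nutrient_mult:g}")
    model = _make_model(cfg, case, comps)
    model.forcing.pulse = flat
    state = OceanState.rest(grid, initial, with_rotation=phys.f != 0.0)
    if days > 0:
        state = model.integrate(state, days * 86400.0)
    state.t = 0.0
    _cache[key] = state.copy()
    return state


@dataclass
class CaseRun:
    """Everything recorded for one flood simulation."""

    case: CaseSpec
    series: SurfaceSeries                 # raw hourly top-slab fields
    budgets: dict
    config_hash: str
    final_state: OceanState | None = None
    snapshots: list | None = None         # optional full-field dumps


# SurfaceSeries is the diagnostics-facing record; reuse its shape here.
def run_case(cfg: RunConfig, case: CaseSpec, *, save_state: bool = False,
             snapshot_every_h: float | None = None) -> CaseRun:
    """Simulate the flood window for one sensitivity case.

    Returns the hourly surface record plus the budget-closure report.
    Deterministic: identical (config, case) give identical output bytes.
    """
    comps = _components(cfg)
    grid = comps[0]
    model = _make_model(cfg, case, comps)
    state = spinup(cfg, case.nutrient_mult)

    nsl = max(cfg.diagnostics.surface_layers, 2)
    rec = {"t": [], "S": [], "N": [], "P": [], "C": []}
    snaps = [] if snapshot_every_h else None

    def observer(s: OceanState):
        rec["t"].append(s.t)
        rec["S"].append(s.S[:nsl, :].copy())
        rec["N"].append(s.N[:nsl, :].copy())
        rec["P"].append(s.P[:nsl, :].copy())
        rec["C"].append(s.C[:nsl, :].copy())
        if snaps is not None and (s.t / 3600.0) % snapshot_every_h < 1e-9:
            snaps.append(s.copy())

    state0 = state.copy()
    cadence = cfg.output.cadence_h * 3600.0
    state = model.integrate(state, cfg.scenario.duration_h * 3600.0,
                            observer=observer, obs_interval=cadence)
    series = SurfaceSeries(case=case, times=np.array(rec["t"]),
                           S=np.array(rec["S"]), N=np.array(rec["N"]),
                           P=np.array(rec["P"]), C=np.array(rec["C"]),
                           grid=grid)
    budgets = model.closure_report(state0, state)
    return CaseRun(case=case, series=series, budgets=budgets,
                   config_hash=cfg.hash(),
                   final_state=state if save_state else None,
                   snapshots=snaps)


def default_sweep_cases() -> list[CaseSpec]:
    """Reduced sensitivity grid: ssm {0,1,2,4,6,8,10} x d {10,20,50} um."""
    return case_grid([0, 1, 2, 4, 6, 8, 10],
                     [1.0e-5, 2.0e-5, 5.0e-5], [1.0])


def extended_sweep_cases() -> list[CaseSpec]:
    """Default grid extended with nutrient multipliers {0.1, 1, 10}."""
    return case_grid([0, 1, 2, 4, 6, 8, 10],
                     [1.0e-5, 2.0e-5, 5.0e-5], [0.1, 1.0, 10.0])


@dataclass
class SweepResult:
    cases: list
    series: dict          # label -> PlumeSeries (difference series)
    runs: dict            # label -> CaseRun
    regime_maps: dict     # nutrient_mult -> RegimeMap
    manifest: dict


def run_sweep(cfg: RunConfig, cases: list[CaseSpec] | None = None, *,
              outdir: str | Path | None = None, resume: bool = True,
              progress=None) -> SweepResult:
    """Run every case, difference it against its WOS, build regime maps.

    ``outdir`` (optional) receives per-case plume-series CSVs, regime-map
    CSVs with JSON sidecars, and a manifest; an existing manifest with
    matching config hash lets a crashed sweep resume from its CSVs.
    """
    if cases is None:
        cases = default_sweep_cases()
    pp = build_plume_params(cfg)
    comps = _components(cfg)
    grid, phys, bio, initial, std, pulse, sponge = comps
    chash = cfg.hash()

    out = Path(outdir) if outdir is not None else None
    manifest_path = out / "manifest.json" if out else None
    manifest = {"config_hash": chash, "code_version": _code_version,
                "created": time.strftime("%Y-%m-%dT%H:%M:%S"), "cases": {}}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if resume and manifest_path.exists():
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == chash:
                manifest["cases"] = old.get("cases", {})

    # WOS references first, one per nutrient level
    nut_levels = sorted({c.nutrient_mult for c in cases})
    wos_runs: dict[float, CaseRun] = {}
    runs: dict[str, CaseRun] = {}
    series: dict[str, PlumeSeries] = {}

    ordered = ([c for c in cases if c.is_wos] + [c for c in cases if not c.is_wos])
    for case in ordered:
        label = case.label
        csv_path = out / f"plume_{label}.csv" if out else None
        cached = (resume and label in manifest["cases"]
                  and manifest["cases"][label].get("status") == "done"
                  and csv_path is not None and csv_path.exists()
                  and not case.is_wos)
        run = None
        if not cached:
            run = run_case(cfg, case)
            runs[label] = run
            if case.is_wos:
                wos_runs[case.nutrient_mult] = run
        if progress:
            progress(label, cached)

        if run is not None:
            ps = difference_series(run.series, wos_runs[case.nutrient_mult].series, pp)
            series[label] = ps
            if out is not None:
                ps.to_csv(csv_path)
                manifest["cases"][label] = {
                    "status": "done", "outputs": [csv_path.name],
                    "budget_closure": {k: v["relative"] if isinstance(v, dict) else v
                                       for k, v in run.budgets.items()
                                       if isinstance(v, dict)},
                    "max_div": run.budgets.get("max_div"),
                }
                manifest_path.write_text(json.dumps(manifest, indent=1))
        else:
            tab = pd.read_csv(csv_path)
            extrema = {name: _ext_from_tab(tab, name) for name in ("S", "N", "P")}
            series[label] = PlumeSeries(case=case, table=tab, extrema=extrema)

    # regime maps per nutrient level
    regime_maps = {}
    for n in nut_levels:
        sub = [(c, series[c.label]) for c in cases if c.nutrient_mult == n]
        mults = sorted({c.ssm_mult for c, _ in sub})
        dens = [river_density_difference(
            CaseSpec(m, 1e-5 if m > 0 else None, n), std, pulse.peak_Q,
            cfg.scenario.T_river,
            initial.T[0], initial.S[0], phys) for m in mults]
        rm = build_regime_map(sub, pp, density_axis=dens, nutrient_mult=n)
        regime_maps[n] = rm
        if out is not None:
            rm.to_dataframe().to_csv(out / f"regime_map_n{n:g}.csv")
            (out / f"regime_map_n{n:g}.json").write_text(
                json.dumps(rm.sidecar(), indent=1))

    if out is not None:
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return SweepResult(cases=cases, series=series, runs=runs,
                       regime_maps=regime_maps, manifest=manifest)


def _ext_from_tab(tab: pd.DataFrame, name: str) -> dict:
    d = tab[f"d{name}"].to_numpy()
    t = tab["time"].to_numpy()
    ok = np.isfinite(d)
    if not ok.any():
        return {"time": float("nan"), "value": float("nan")}
    i = int(np.argmax(np.where(ok, np.abs(d), -1.0)))
    return {"time": float(t[i]), "value": float(d[i])}
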