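"""Plume diagnostics: masking, plume means, WOS differences, regime maps.

The analysis layer mirrors how sediment-laden flood plumes are summarised
in the field: all statistics are taken over the "river plume", the cells
of the top ~2 m (top two model layers by default) whose salinity is at or
below 28 psu, and every effect is measured as a difference from the
matching no-sediment reference (WOS) at the same output times.  The
regime of each sensitivity case is read off the sign of that salinity
difference at the time of its largest magnitude: fresher than WOS means
an intensified hypopycnal (surface-trapped) plume, saltier means the
plume has gone hyperpycnal/homopycnal (sediment-driven sinking or
mixing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid
from .physics import PhysParams, equation_of_state
from .scenario import CaseSpec, StdInputs

__all__ = [
    "PlumeParams", "PlumeSeries", "RegimeMap",
    "plume_mask", "plume_mean", "surface_series", "difference_series",
    "regime_classify", "river_density_difference", "build_regime_map",
    "relative_change",
]

HYPOPYCNAL = "hypopycnal"
HYPERPYCNAL = "hyperpycnal"
NEUTRAL = "neutral"


class EmptyMaskError(ValueError):
    """Plume mean requested over an empty mask."""


@dataclass(frozen=True)
class PlumeParams:
    """How the plume is delimited for averaging."""

    salinity_threshold: float = 28.0    # [psu]; cells with S <= threshold
    surface_layers: int = 2             # top layers forming the surface slab
    mask_source: str = "reference"      # mask from the reference run; or "per-case"
    neutral_tol: float = 0.01           # [psu] regime dead-band

    def __post_init__(self) -> None:
        if self.salinity_threshold <= 0 or self.surface_layers < 1:
            raise ValueError("invalid plume parameters")
        if self.mask_source not in ("per-case", "reference"):
            raise ValueError("mask_source must be 'per-case' or 'reference'")


def plume_mask(state, pp: PlumeParams, reference_state=None) -> np.ndarray:
    """Boolean (surface_layers, nx) mask of plume cells.

    A cell is in the plume iff it lies in the top ``surface_layers``
    layers and the salinity of the designated source state (the case
    itself, or the reference run when ``mask_source='reference'``) is at
    or below the threshold (S = 28.0 exactly is inside).
    """
    if pp.mask_source == "reference":
        if reference_state is None:
            raise ValueError("mask_source='reference' needs a reference state")
        S = reference_state.S
    else:
        S = state.S
    return np.asarray(S)[: pp.surface_layers, :] <= pp.salinity_threshold


def plume_mean(field, mask, grid: Grid) -> float:
    """Volume-weighted mean of ``field`` over the masked surface cells."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("plume mask is empty")
    nsl = mask.shape[0]
    w = (grid.dz[:nsl, None] * grid.dx) * mask
    f = np.asarray(field)[:nsl, :]
    return float((f * w).sum() / w.sum())


@dataclass
class SurfaceSeries:
    """Hourly top-slab fields recorded during a run (one case)."""

    case: CaseSpec
    times: np.ndarray                  # [s]
    S: np.ndarray                      # (nt, nsl, nx)
    N: np.ndarray
    P: np.ndarray
    C: np.ndarray | None = None
    grid: Grid | None = None


def surface_series(results, pp: PlumeParams, reference=None) -> pd.DataFrame:
    """Plume-masked means per output time for one recorded run.

    Returns a DataFrame with time [s], plume width [m], and mean S, N, P.
    Times where the mask is empty carry NaN (recorded as missing, never
    zero) and are excluded from extremum searches downstream.
    """
    grid = results.grid
    nsl = pp.surface_layers
    src = reference if (pp.mask_source == "reference" and reference is not None) else results
    Smask = src.S[:, :nsl, :] <= pp.salinity_threshold
    w = (grid.dz[:nsl, None] * grid.dx) * np.ones((1, grid.nx))
    rows = {}
    wm = Smask * w[None, :, :]
    wsum = wm.sum(axis=(1, 2))
    empty = wsum == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in ("S", "N", "P"):
            f = getattr(results, name)[:, :nsl, :]
            rows[name] = np.where(empty, np.nan, (f * wm).sum(axis=(1, 2)) / wsum)
    area = Smask.any(axis=1).sum(axis=1) * grid.dx   # plume width [m]
    return pd.DataFrame({
        "time": results.times, "area": area,
        "S": rows["S"], "N": rows["N"], "P": rows["P"]})


@dataclass
class PlumeSeries:
    """Difference-from-reference plume statistics for one case."""

    case: CaseSpec
    table: pd.DataFrame   # time, area, S, N, P, S_ref, N_ref, P_ref, dS, dN, dP
    extrema: dict         # per variable: time and value of max |d|

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _extremum(times, d):
    ok = np.isfinite(d)
    if not ok.any():
        return {"time": np.nan, "value": np.nan}
    mag = np.where(ok, np.abs(d), -1.0)    # masked samples can never win
    i = int(np.argmax(mag))
    return {"time": float(times[i]), "value": float(d[i])}


def difference_series(case_run, wos_run, pp: PlumeParams) -> PlumeSeries:
    """Plume-mean differences case - reference at matched output times.

    Both runs must share the output time grid and model grid.  Under
    per-case masking each run is averaged over its own plume; under
    reference masking both use the reference run's plume.
    """
    if (len(case_run.times) != len(wos_run.times)
            or not np.allclose(case_run.times, wos_run.times)):
        raise ValueError("output time grids do not match")
    tc = surface_series(case_run, pp, reference=wos_run)
    tw = surface_series(wos_run, pp, reference=wos_run)
    tab = tc.copy()
    for name in ("S", "N", "P"):
        tab[f"{name}_ref"] = tw[name]
        tab[f"d{name}"] = tc[name] - tw[name]
    extrema = {name: _extremum(tab["time"].to_numpy(),
                               tab[f"d{name}"].to_numpy())
               for name in ("S", "N", "P")}
    return PlumeSeries(case=case_run.case, table=tab, extrema=extrema)


def regime_classify(delta_s: float, tol: float = 0.01) -> str:
    """Label a salinity difference: fresher -> hypopycnal, saltier -> hyperpycnal."""
    if not np.isfinite(delta_s):
        raise ValueError("salinity difference must be finite")
    if delta_s < -tol:
        return HYPOPYCNAL
    if delta_s > tol:
        return HYPERPYCNAL
    return NEUTRAL


def river_density_difference(case: CaseSpec, std: StdInputs, peak_Q: float,
                             T_river: float, T_ambient: float, S_ambient: float,
                             phys: PhysParams) -> float:
    """Predicted river-minus-sea density difference [kg/m^3] for a case.

    Computed from the maximum SSM input (at peak discharge), fresh river
    water versus the ambient surface state; independent of the particle
    diameter by construction.
    """
    C_peak = case.ssm_mult * std.c_std(peak_Q)
    rho_riv = float(equation_of_state(T_river, 0.0, C_peak, phys))
    rho_amb = float(equation_of_state(T_ambient, S_ambient, 0.0, phys))
    return rho_riv - rho_amb


@dataclass
class RegimeMap:
    """Sensitivity grid of salinity-difference outcomes.

    ``value[j, i]`` is the plume-mean salinity difference at the time of
    its largest magnitude for diameter j and SSM multiplier i;
    ``label`` holds the regime classification, and ``transition`` the
    bracketing multiplier interval where the sign flips, per diameter.
    """

    ssm_mults: np.ndarray
    diameters: np.ndarray
    value: np.ndarray          # (n_diam, n_ssm) [psu]
    label: np.ndarray          # (n_diam, n_ssm) of str
    extremum_time: np.ndarray  # (n_diam, n_ssm) [s]
    density_axis: np.ndarray | None = None   # (n_ssm,) predicted drho [kg/m^3]
    transition: dict = field(default_factory=dict)  # diameter -> (lo, hi) or None
    nutrient_mult: float = 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.value, index=[f"{d*1e3:g}mm" for d in self.diameters],
                            columns=[f"{m:g}" for m in self.ssm_mults])

    def sidecar(self) -> dict:
        return {
            "ssm_mults": self.ssm_mults.tolist(),
            "diameters_m": self.diameters.tolist(),
            "nutrient_mult": self.nutrient_mult,
            "labels": self.label.tolist(),
            "extremum_time_s": self.extremum_time.tolist(),
            "density_axis_kg_m3": (None if self.density_axis is None
                                   else self.density_axis.tolist()),
            "transition_intervals": {f"{d*1e3:g}mm": v
                                     for d, v in self.transition.items()},
        }


def build_regime_map(runs, pp: PlumeParams, *, density_axis=None,
                     nutrient_mult: float = 1.0) -> RegimeMap:
    """Assemble the (diameter x SSM multiplier) regime map from case series.

    ``runs`` is an iterable of (CaseSpec, PlumeSeries) covering a full
    rectangular grid for one nutrient multiplier; missing cells raise
    with the offending combination listed.  A zero multiplier column (the
    WOS itself) is allowed and is identically zero/neutral.
    """
    runs = list(runs)
    mults = sorted({r[0].ssm_mult for r in runs})
    diams = sorted({r[0].diameter for r in runs if r[0].diameter is not None})
    if not diams:
        diams = [np.nan]
    value = np.full((len(diams), len(mults)), np.nan)
    etime = np.full((len(diams), len(mults)), np.nan)
    have = {}
    for case, series in runs:
        ext = series.extrema["S"]
        if case.is_wos:
            for j in range(len(diams)):
                if 0.0 in mults:
                    i = mults.index(0.0)
                    value[j, i] = ext["value"]
                    etime[j, i] = ext["time"]
                    have[(j, i)] = True
            continue
        j = diams.index(case.diameter)
        i = mults.index(case.ssm_mult)
        value[j, i] = ext["value"]
        etime[j, i] = ext["time"]
        have[(j, i)] = True
    missing = [(diams[j], mults[i]) for j in range(len(diams))
               for i in range(len(mults)) if (j, i) not in have]
    if missing:
        raise ValueError(f"incomplete sensitivity grid; missing cells: {missing}")

    tol = pp.neutral_tol
    label = np.empty(value.shape, dtype=object)
    for j in range(len(diams)):
        for i in range(len(mults)):
            v = value[j, i]
            # a cell whose plume never formed is recorded missing, not zero
            label[j, i] = regime_classify(v, tol) if np.isfinite(v) else "missing"

    transition = {}
    for j, d in enumerate(diams):
        interval = None
        row = value[j]
        for i in range(len(mults) - 1):
            if row[i] < -tol and row[i + 1] > tol:
                interval = (mults[i], mults[i + 1])
                break
        transition[d] = interval

    return RegimeMap(ssm_mults=np.array(mults), diameters=np.array(diams),
                     value=value, label=label, extremum_time=etime,
                     density_axis=(None if density_axis is None
                                   else np.asarray(density_axis, float)),
                     transition=transition, nutrient_mult=nutrient_mult)


def decay_fraction(series: PlumeSeries, t_peak: float,
                   after: float = 72 * 3600.0, variable: str = "S") -> float:
    """|d| a few days after the flood peak, as a fraction of its maximum.

    Evaluated on the last valid sample in the window
    [t_peak + 0.75*after, t_peak + after]; if the plume has dissolved by
    then (mask empty, all samples missing) the difference has fully
    decayed and the fraction is 0."""
    tab = series.table
    t = tab["time"].to_numpy()
    d = tab[f"d{variable}"].to_numpy()
    mx = np.nanmax(np.abs(d))
    if not np.isfinite(mx) or mx == 0.0:
        return 0.0
    sel = (t >= t_peak + 0.75 * after) & (t <= t_peak + after) & np.isfinite(d)
    if not sel.any():
        return 0.0
    return float(np.abs(d[sel][-1]) / mx)


def relative_change(series: PlumeSeries, variable: str = "S") -> float:
    """Percent change |d| / reference at the time of the extremum.

    100 * |dX(t*)| / X_ref(t*) with t* the time of max |dX|; NaN if the
    series never has a valid masked mean."""
    ext = series.extrema[variable]
    if not np.isfinite(ext["time"]):
        return float("nan")
    tab = series.table
    i = int(np.argmin(np.abs(tab["time"].to_numpy() - ext["time"])))
    ref = float(tab[f"{variable}_ref"].iloc[i])
    if not np.isfinite(ref) or ref == 0.0:
        return float("nan")
    return 100.0 * abs(ext["value"]) / abs(ref)
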