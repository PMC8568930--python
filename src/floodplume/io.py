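"""NetCDF output of model fields and restarts (CF-style, via xarray).

Snapshots are written with dimension order (time, z, x), coordinates in
metres and unit attributes matching the state definitions.  Field dumps
use single precision to keep files small; restarts keep full double
precision so a restarted trajectory is bitwise-continuable.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grid import Grid
from .model import OceanState, TRACERS

_UNITS = {"T": "degC", "S": "psu", "C": "kg m-3", "N": "mol m-3",
          "P": "mol m-3", "Z": "mol m-3", "Dt": "mol m-3"}


def _coords(grid: Grid) -> dict:
    return {
        "z": ("z", grid.z_c, {"units": "m", "positive": "down",
                              "long_name": "cell-centre depth"}),
        "x": ("x", (np.arange(grid.nx) + 0.5) * grid.dx,
              {"units": "m", "long_name": "offshore distance"}),
    }


def states_to_dataset(states: list[OceanState], grid: Grid,
                      chl_per_N: float | None = None,
                      deposit: np.ndarray | None = None) -> xr.Dataset:
    """Stack snapshots into one (time, z, x) dataset of tracers.

    Velocities are interpolated onto cell centres for output; a derived
    chlorophyll-a variable is added when a conversion factor is given,
    and the per-column deposited sediment mass when a ledger is given.
    """
    t = np.array([s.t for s in states])
    data = {}
    for name in TRACERS:
        arr = np.stack([np.asarray(getattr(s, name), dtype=np.float32)
                        for s in states])
        data[name] = (("time", "z", "x"), arr, {"units": _UNITS[name]})
    u_cc = np.stack([0.5 * (s.u[:, 1:] + s.u[:, :-1]) for s in states]).astype(np.float32)
    w_cc = np.stack([0.5 * (s.w[1:, :] + s.w[:-1, :]) for s in states]).astype(np.float32)
    data["u"] = (("time", "z", "x"), u_cc, {"units": "m s-1"})
    data["w"] = (("time", "z", "x"), w_cc, {"units": "m s-1"})
    if chl_per_N is not None:
        # mol N/m^3 -> umol N/l is a factor 1000
        chla = data["P"][1] * 1000.0 * chl_per_N
        data["chla"] = (("time", "z", "x"), chla, {"units": "ug chla l-1"})
    if deposit is not None:
        dep = np.asarray(deposit, dtype=np.float32)
        data["deposit"] = (("x",), dep, {"units": "kg m-2",
                                         "long_name": "deposited SSM mass"})
    ds = xr.Dataset(data, coords=_coords(grid))
    ds = ds.assign_coords(time=("time", t, {"units": "s"}))
    return ds


def write_snapshots(path, states, grid: Grid, **kw) -> None:
    states_to_dataset(states, grid, **kw).to_netcdf(path, engine="scipy")


def save_restart(path, state: OceanState, grid: Grid) -> None:
    data = {n: (("z", "x"), getattr(state, n)) for n in TRACERS}
    data["u"] = (("z", "xf"), state.u)
    data["w"] = (("zf", "x"), state.w)
    if state.v is not None:
        data["v"] = (("z", "xf"), state.v)
    if state.eta is not None:
        data["eta"] = (("x",), state.eta)
    ds = xr.Dataset(data, coords=_coords(grid), attrs={"t": state.t})
    ds.to_netcdf(path, engine="scipy")


def load_restart(path, grid: Grid) -> OceanState:
    with xr.open_dataset(path, engine="scipy") as ds:
        kw = {n: ds[n].values.copy() for n in TRACERS}
        return OceanState(
            t=float(ds.attrs["t"]), u=ds["u"].values.copy(),
            w=ds["w"].values.copy(),
            eta=ds["eta"].values.copy() if "eta" in ds else None,
            v=ds["v"].values.copy() if "v" in ds else None, **kw)
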