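"""Staggered 2-D (x–z) model grid.

Conventions (fixed for the whole package):

* ``x`` is the along-plume coordinate, positive offshore, cell index ``i``.
* ``z`` is positive upward; layer ``k = 0`` is the surface layer.  Layer
  thicknesses ``dz[k]`` are stored surface-first; interface and centre
  *depths* (``z_w``, ``z_c``) are positive numbers measured downward from
  the rigid lid, which is the natural bookkeeping for light attenuation
  and settling.
* Tracers and pressure live at cell centres, shape ``(nz, nx)``.
* Horizontal velocity ``u`` lives on x-faces, shape ``(nz, nx + 1)``.
* Vertical velocity ``w`` lives on z-faces, shape ``(nz + 1, nx)``;
  ``w[k]`` is the face *above* cell ``k`` and positive ``w`` is upward.

Columns may be shallower than ``sum(dz)``: the per-column bottom depth
``H[i]`` is snapped to the nearest layer interface and cells below it are
masked out (land/seafloor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True, eq=False)
class Grid:
    """Geometry of the vertical-slice domain.

    Parameters
    ----------
    nx : int
        Number of columns along the plume axis.
    dx : float
        Horizontal cell size [m].
    dz : ndarray, shape (nz,)
        Layer thicknesses, surface layer first [m].  The default scenario
        uses a 1 m surface layer so the "top two layers" diagnostic slab
        is ~2 m thick.
    H : ndarray, shape (nx,)
        Bottom depth per column [m]; snapped to layer interfaces.
    orientation : str
        Convention flag (documentation only).
    """

    nx: int
    dx: float
    dz: np.ndarray
    H: np.ndarray
    orientation: str = "z-up,surface-first,x-offshore"

    # derived, filled in __post_init__
    nz: int = field(init=False)
    z_w: np.ndarray = field(init=False)   # (nz+1,) interface depths, z_w[0]=0
    z_c: np.ndarray = field(init=False)   # (nz,)   centre depths
    dzf: np.ndarray = field(init=False)   # (nz+1,) centre-to-centre spacing at z-faces
    kbot: np.ndarray = field(init=False)  # (nx,)   active layer count per column
    mask: np.ndarray = field(init=False)  # (nz,nx) True where wet

    def __post_init__(self) -> None:
        dz = np.asarray(self.dz, dtype=float)
        H = np.asarray(self.H, dtype=float)
        if dz.ndim != 1 or dz.size < 4:
            raise ValueError("need at least 4 vertical layers")
        if np.any(dz <= 0) or self.dx <= 0:
            raise ValueError("grid spacings must be positive")
        if H.shape != (self.nx,):
            raise ValueError("H must have one depth per column")
        if np.any(H <= 0):
            raise ValueError("bottom depths must be positive")
        nz = dz.size
        z_w = np.concatenate([[0.0], np.cumsum(dz)])
        if z_w[-1] < H.max() - 1e-9:
            raise ValueError("sum(dz) must cover the deepest column")
        # snap each column's depth to the nearest interface, at least 1 layer
        kbot = np.array([int(np.argmin(np.abs(z_w[1:] - h))) + 1 for h in H])
        kbot = np.clip(kbot, 1, nz)
        mask = np.arange(nz)[:, None] < kbot[None, :]
        z_c = z_w[:-1] + 0.5 * dz
        # centre-to-centre distance across each interior z-face; end faces
        # get the half-cell distance (used only for Neumann metrics)
        dzf = np.empty(nz + 1)
        dzf[1:-1] = z_c[1:] - z_c[:-1]
        dzf[0] = 0.5 * dz[0]
        dzf[-1] = 0.5 * dz[-1]
        object.__setattr__(self, "dz", dz)
        object.__setattr__(self, "H", z_w[kbot])
        object.__setattr__(self, "nz", nz)
        object.__setattr__(self, "z_w", z_w)
        object.__setattr__(self, "z_c", z_c)
        object.__setattr__(self, "dzf", dzf)
        object.__setattr__(self, "kbot", kbot)
        object.__setattr__(self, "mask", mask)

    # -- constructors -------------------------------------------------

    @classmethod
    def uniform(cls, nx: int, dx: float, dz: np.ndarray) -> "Grid":
        """Flat-bottom grid spanning the full layer stack everywhere."""
        dz = np.asarray(dz, dtype=float)
        H = np.full(nx, dz.sum())
        return cls(nx=nx, dx=dx, dz=dz, H=H)

    @classmethod
    def sloping(cls, nx: int, dx: float, dz: np.ndarray,
                h_inshore: float, h_offshore: float) -> "Grid":
        """Linear shelf: depth ramps from the river end to the open end."""
        x = (np.arange(nx) + 0.5) * dx
        H = h_inshore + (h_offshore - h_inshore) * x / (nx * dx)
        return cls(nx=nx, dx=dx, dz=np.asarray(dz, float), H=H)

    # -- helpers ------------------------------------------------------

    @property
    def cell_volume(self) -> np.ndarray:
        """(nz, nx) unit-width cell volumes [m^3 per m], zero on land."""
        return np.where(self.mask, self.dz[:, None] * self.dx, 0.0)

    def column_depth(self, i: int) -> float:
        return float(self.z_w[self.kbot[i]])
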