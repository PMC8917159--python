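"""Staggered (MAC) grid container for the 2D flow core.

Velocity components live on cell faces, pressure and viscosity at cell
centers.  Coordinates are in um, velocities in um/ms, pressure in Pa and
viscosity in Pa*ms (see :mod:`hemonet.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StaggeredGrid:
    """Uniform MAC grid over the rectangle ``[x0, x0+nx*h] x [y0, y0+ny*h]``."""

    x0: float
    y0: float
    nx: int
    ny: int
    h: float

    @property
    def lx(self) -> float:
        return self.nx * self.h

    @property
    def ly(self) -> float:
        return self.ny * self.h

    def p_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates, shapes (nx, ny)."""
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.h
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y, indexing="ij")

    def u_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """x-face coordinates (u nodes), shapes (nx+1, ny)."""
        x = self.x0 + np.arange(self.nx + 1) * self.h
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y, indexing="ij")

    def v_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """y-face coordinates (v nodes), shapes (nx, ny+1)."""
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.h
        y = self.y0 + np.arange(self.ny + 1) * self.h
        return np.meshgrid(x, y, indexing="ij")


@dataclass
class FluidState:
    """Velocity/pressure/viscosity fields on a staggered grid.

    ``u`` has shape (nx+1, ny), ``v`` (nx, ny+1), ``p`` and ``mu``
    (nx, ny).  ``time_ms`` is the simulation clock.
    """

    grid: StaggeredGrid
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mu: np.ndarray
    time_ms: float = 0.0

    @classmethod
    def zeros(cls, grid: StaggeredGrid, mu_plasma: float) -> "FluidState":
        return cls(
            grid=grid,
            u=np.zeros((grid.nx + 1, grid.ny)),
            v=np.zeros((grid.nx, grid.ny + 1)),
            p=np.zeros((grid.nx, grid.ny)),
            mu=np.full((grid.nx, grid.ny), float(mu_plasma)),
        )

    def copy(self) -> "FluidState":
        return FluidState(self.grid, self.u.copy(), self.v.copy(),
                          self.p.copy(), self.mu.copy(), self.time_ms)

    def divergence(self) -> np.ndarray:
        """Discrete divergence at cell centers, shape (nx, ny)."""
        h = self.grid.h
        return (self.u[1:, :] - self.u[:-1, :]) / h + (self.v[:, 1:] - self.v[:, :-1]) / h

    def interp_velocity(self, points: np.ndarray) -> np.ndarray:
        """Bilinear velocity interpolation at ``points`` (n, 2) -> (n, 2)."""
        pts = np.atleast_2d(points)
        out = np.empty_like(pts, dtype=float)
        out[:, 0] = _bilinear(self.u, pts, self.grid.x0, self.grid.y0 + 0.5 * self.grid.h,
                              self.grid.h)
        out[:, 1] = _bilinear(self.v, pts, self.grid.x0 + 0.5 * self.grid.h, self.grid.y0,
                              self.grid.h)
        return out


def _bilinear(f: np.ndarray, pts: np.ndarray, ox: float, oy: float, h: float) -> np.ndarray:
    """Bilinear sample of array ``f`` whose node (i, j) sits at (ox+i*h, oy+j*h)."""
    gx = (pts[:, 0] - ox) / h
    gy = (pts[:, 1] - oy) / h
    i0 = np.clip(np.floor(gx).astype(int), 0, f.shape[0] - 2)
    j0 = np.clip(np.floor(gy).astype(int), 0, f.shape[1] - 2)
    tx = np.clip(gx - i0, 0.0, 1.0)
    ty = np.clip(gy - j0, 0.0, 1.0)
    return ((1 - tx) * (1 - ty) * f[i0, j0] + tx * (1 - ty) * f[i0 + 1, j0]
            + (1 - tx) * ty * f[i0, j0 + 1] + tx * ty * f[i0 + 1, j0 + 1])
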