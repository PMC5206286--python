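"""Prescribed nucleus field and grid geometry.

The nucleus is not a dynamical field: it is an elliptical (or circular)
indicator ``phi0`` — 0 inside, 1 outside, with a thin tanh interface — whose
semi-axes may follow a linear shrink/deformation schedule.  The chromatin
fields never feed back on it.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .model import interp_h


@dataclasses.dataclass(frozen=True)
class Grid:
    """Cell-centered regular grid on the rectangle [-Lx/2, Lx/2] x [-Ly/2, Ly/2].

    Fields are stored as arrays of shape ``(ny, nx)`` indexed ``[j, i]`` with
    ``x = x[i]``, ``y = y[j]``.  All volume integrals are midpoint Riemann
    sums with weight ``dx * dy``.
    """

    nx: int
    ny: int
    Lx: float = 1.2
    Ly: float = 1.8

    @property
    def dx(self) -> float:
        return self.Lx / self.nx

    @property
    def dy(self) -> float:
        return self.Ly / self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx - 0.5 * self.Lx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy - 0.5 * self.Ly

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable (X, Y) cell-center coordinates, each (ny, nx)."""
        return np.meshgrid(self.x, self.y)


@dataclasses.dataclass(frozen=True)
class NucleusGeometry:
    """Time-parameterized elliptical nucleus.

    Semi-axes interpolate linearly from ``(axis_x0, axis_y0)`` to
    ``(axis_x1, axis_y1)`` over the window ``[t_start, t_end]`` and are
    constant outside it; equal endpoints (or an empty window) give a static
    nucleus.  ``eps0`` is the squared interface-width parameter of the tanh
    profile (the analogue of eps^2 for the prescribed field).
    """

    axis_x0: float = 0.5
    axis_y0: float = 0.8
    axis_x1: float = 0.5
    axis_y1: float = 0.8
    t_start: float = 0.0
    t_end: float = 0.0
    eps0: float = 2e-5

    def __post_init__(self) -> None:
        if min(self.axis_x0, self.axis_y0, self.axis_x1, self.axis_y1) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")
        if self.eps0 <= 0:
            raise ValueError("eps0 must be positive")

    @property
    def static(self) -> bool:
        return (self.axis_x0 == self.axis_x1 and self.axis_y0 == self.axis_y1) \
            or self.t_start == self.t_end

    @classmethod
    def shrink_to(cls, axis_x0: float, axis_y0: float, area_fraction: float,
                  final_shape: str = "circle", t_start: float = 0.0,
                  t_end: float = 0.0, eps0: float = 2e-5) -> "NucleusGeometry":
        """Schedule shrinking the nuclear area to ``area_fraction`` of its
        initial value, ending as a circle of equal area or as a scaled ellipse.
        """
        if not 0 < area_fraction <= 1:
            raise ValueError("area_fraction must lie in (0, 1]")
        if final_shape == "circle":
            radius = float(np.sqrt(area_fraction * axis_x0 * axis_y0))
            ax1, ay1 = radius, radius
        elif final_shape == "ellipse":
            s = float(np.sqrt(area_fraction))
            ax1, ay1 = s * axis_x0, s * axis_y0
        else:
            raise ValueError(f"unknown final_shape {final_shape!r}")
        return cls(axis_x0, axis_y0, ax1, ay1, t_start, t_end, eps0)


def geometry_at(geom: NucleusGeometry, t: float) -> tuple[float, float]:
    """Semi-axes at time ``t`` (linear interpolation over the shrink window)."""
    if t <= geom.t_start or geom.static:
        return geom.axis_x0, geom.axis_y0
    if t >= geom.t_end:
        return geom.axis_x1, geom.axis_y1
    s = (t - geom.t_start) / (geom.t_end - geom.t_start)
    return (geom.axis_x0 + s * (geom.axis_x1 - geom.axis_x0),
            geom.axis_y0 + s * (geom.axis_y1 - geom.axis_y0))


def elliptical_radius(grid: Grid, axis_x: float, axis_y: float) -> np.ndarray:
    """Normalized elliptical coordinate r = sqrt((x/a)^2 + (y/b)^2)."""
    X, Y = grid.mesh()
    return np.sqrt((X / axis_x) ** 2 + (Y / axis_y) ** 2)


def signed_level_distance(grid: Grid, axis_x: float, axis_y: float) -> np.ndarray:
    """Signed-distance surrogate to the ellipse, positive outside.

    The level-set function r(x) - 1 is rescaled by its local gradient
    magnitude, which approximates the true signed distance to well within the
    interface width used here.
    """
    X, Y = grid.mesh()
    r = np.sqrt((X / axis_x) ** 2 + (Y / axis_y) ** 2)
    grad = np.sqrt((X / axis_x ** 2) ** 2 + (Y / axis_y ** 2) ** 2)
    inner = min(axis_x, axis_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(grad > 1e-12, (r - 1.0) * r / np.maximum(grad, 1e-300),
                     -inner)
    return s


def make_phi0(geom: NucleusGeometry, t: float, grid: Grid) -> np.ndarray:
    """Nucleus field phi0 at time ``t``: 1/2 [1 + tanh(s / (2 sqrt(2) sqrt(eps0)))].

    ``phi0`` is ~0 deep inside the nucleus, ~1 deep outside and exactly 1/2 on
    the ellipse.  Warns when the interface spans fewer than 4 grid cells.
    """
    ax, ay = geometry_at(geom, t)
    margin = 3.0 * 2.0 * np.sqrt(2.0 * geom.eps0)
    if ax + margin > 0.5 * grid.Lx or ay + margin > 0.5 * grid.Ly:
        raise ValueError(
            f"nucleus semi-axes ({ax:.3g}, {ay:.3g}) do not fit the domain "
            f"{grid.Lx} x {grid.Ly} with a 3-interface-width margin")
    width = 2.0 * np.sqrt(2.0) * np.sqrt(geom.eps0)   # tanh argument scale
    band = 2.0 * width * np.arctanh(0.7)              # 0.15..0.85 transition
    if band < 4.0 * min(grid.dx, grid.dy):
        warnings.warn(
            f"nucleus interface band {band:.3g} spans fewer than 4 cells "
            f"(dx={grid.dx:.3g}); increase eps0 or refine the grid",
            RuntimeWarning, stacklevel=2)
    s = signed_level_distance(grid, ax, ay)
    return 0.5 * (1.0 + np.tanh(s / width))


def nuclear_volume(phi0: np.ndarray, grid: Grid) -> float:
    """Nuclear volume ∫ [1 - h(phi0)] dx as a midpoint Riemann sum."""
    return float((1.0 - interp_h(phi0)).sum() * grid.cell_area)
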