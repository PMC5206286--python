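"""Explicit finite-difference integration of the chromatin phase-field system.

Forward-Euler time stepping of the reaction-diffusion equations

    d(phi_m)/dt = eps_phi^2 lap(phi_m) + phi_m (1-phi_m) [phi_m - 1/2 - A_m phi_m (1-phi_m)]
    d(psi)/dt   = eps_psi^2 lap(psi)   + psi  (1-psi)   [psi  - 1/2 - B   psi  (1-psi)]

on a regular cell-centered grid with zero-flux (mirror) boundaries and a
5-point central-difference Laplacian.  The nucleus field ``phi0``, the
conversion fraction ``rho_m(t)`` and the volume targets are refreshed at the
start of every step.  A stability guard refuses configurations with

    max(eps_phi^2, eps_psi^2) * (dt/dx^2 + dt/dy^2) > 1/2.

Two equivalent arithmetic paths are provided: vectorized numpy (the
reference) and numba-jitted loops (used by :func:`run` when available).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import Grid, NucleusGeometry, geometry_at, make_phi0, nuclear_volume
from .model import (ConversionSchedule, ModelParams, interp_h, targets_at,
                    total_energy)

logger = logging.getLogger(__name__)

BOUND_LO, BOUND_HI = -0.05, 1.05


class ConfigurationError(ValueError):
    """Raised when a solver configuration violates the stability guard."""


@dataclasses.dataclass
class SimulationState:
    """Fields of the coupled system at time ``t``.

    ``phi`` has shape ``(N, ny, nx)`` (chromosome territories), ``psi`` and
    ``phi0`` shape ``(ny, nx)``.  ``phi0`` is externally prescribed and never
    updated by the gradient flow.
    """

    phi: np.ndarray
    psi: np.ndarray
    phi0: np.ndarray
    t: float
    grid: Grid

    def __post_init__(self) -> None:
        if self.phi.ndim != 3:
            raise ValueError("phi must have shape (N, ny, nx)")
        if self.psi.shape != self.grid.shape or self.phi0.shape != self.grid.shape \
                or self.phi.shape[1:] != self.grid.shape:
            raise ValueError("all fields must share the grid shape (ny, nx)")

    @property
    def n_chrom(self) -> int:
        return self.phi.shape[0]

    def copy(self) -> "SimulationState":
        return SimulationState(self.phi.copy(), self.psi.copy(),
                               self.phi0.copy(), self.t, self.grid)


@dataclasses.dataclass
class SolverConfig:
    """Time step, grid and run-control parameters (non-dimensional units)."""

    dt: float = 6e-4
    nx: int = 200
    ny: int = 300
    Lx: float = 1.2
    Ly: float = 1.8
    t_end: float = 1.0
    record_every: int = 200
    backend: str = "auto"      # "auto" | "numba" | "numpy"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.nx < 1 or self.ny < 1:
            raise ValueError("dt must be positive and grid sizes >= 1")
        if self.backend not in ("auto", "numba", "numpy"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def grid(self) -> Grid:
        return Grid(self.nx, self.ny, self.Lx, self.Ly)


def laplacian(field: np.ndarray, grid: Grid) -> np.ndarray:
    """5-point central-difference Laplacian with mirrored (zero-flux) edges.

    Accepts a single field ``(ny, nx)`` or a stack ``(N, ny, nx)``.
    """
    inv_dx2 = 1.0 / grid.dx ** 2
    inv_dy2 = 1.0 / grid.dy ** 2
    pad = [(0, 0)] * (field.ndim - 2) + [(1, 1), (1, 1)]
    p = np.pad(field, pad, mode="edge")
    c = p[..., 1:-1, 1:-1]
    return ((p[..., 1:-1, :-2] + p[..., 1:-1, 2:] - 2.0 * c) * inv_dx2
            + (p[..., :-2, 1:-1] + p[..., 2:, 1:-1] - 2.0 * c) * inv_dy2)


def stability_factor(cfg: SolverConfig, params: ModelParams) -> float:
    """Diffusive stability factor max(eps^2) * (dt/dx^2 + dt/dy^2)."""
    grid = cfg.grid
    return max(params.eps_phi_sq, params.eps_psi_sq) * (
        cfg.dt / grid.dx ** 2 + cfg.dt / grid.dy ** 2)


def check_stability(cfg: SolverConfig, params: ModelParams) -> float:
    factor = stability_factor(cfg, params)
    if factor > 0.5:
        grid = cfg.grid
        raise ConfigurationError(
            f"stability factor {factor:.4g} > 1/2 for dt={cfg.dt:g}, "
            f"dx={grid.dx:g}, dy={grid.dy:g}, "
            f"max eps^2={max(params.eps_phi_sq, params.eps_psi_sq):g}; "
            f"reduce dt below {0.5 * cfg.dt / factor:.4g}")
    return factor


# ---------------------------------------------------------------------------
# single step (vectorized reference path)
# ---------------------------------------------------------------------------

def _coefficients(V, v, t, params, sched, nuc_vol):
    """Spatially uniform pieces of A_m and B for the current state."""
    V_t, v_t, rho = targets_at(t, sched, V)
    a_scal = (60.0 * params.alpha_V * (V - V_t)
              - 60.0 * params.alpha0 * (nuc_vol - V.sum()))
    c_lin = 60.0 * params.alpha_v * (v - v_t)
    return np.ascontiguousarray(a_scal), np.ascontiguousarray(c_lin), \
        np.ascontiguousarray(rho)


def _euler_numpy(phi, psi, h_phi, h_psi, chi, h0, lap_h0, grid, params,
                 a_scal, c_lin, d_off, dt):
    """Vectorized forward-Euler update; mirrors _kernels arithmetic."""
    base = 30.0 * params.beta0 * h0 - 30.0 * params.beta_psi * h_psi
    A = (a_scal[:, None, None]
         + c_lin[:, None, None] * (h_psi[None] - d_off[:, None, None])
         + 30.0 * params.beta_phi * (chi[None] - h_phi) + base[None])
    w = phi * (1.0 - phi)
    new_phi = phi + (dt * params.mobility_phi) * (
        params.eps_phi_sq * laplacian(phi, grid) + w * (phi - 0.5 - A * w))
    B = ((c_lin[:, None, None] * h_phi).sum(axis=0)
         + 30.0 * params.beta_psi * (1.0 - chi)
         - 30.0 * params.gamma * lap_h0)
    w = psi * (1.0 - psi)
    new_psi = psi + (dt * params.mobility_psi) * (
        params.eps_psi_sq * laplacian(psi, grid) + w * (psi - 0.5 - B * w))
    return new_phi, new_psi


def step(state: SimulationState, params: ModelParams, sched: ConversionSchedule,
         geom: NucleusGeometry, cfg: SolverConfig) -> SimulationState:
    """One forward-Euler step; returns the state at ``t + dt``.

    ``phi0`` is refreshed from the geometry schedule before the reaction
    terms are evaluated; volumes, chi and the nuclear volume are recomputed
    once.  Raises ``RuntimeError`` when the update produces non-finite values.
    """
    check_stability(cfg, params)
    grid = state.grid
    phi0 = make_phi0(geom, state.t, grid) if not geom.static else state.phi0
    h0 = interp_h(phi0)
    lap_h0 = laplacian(h0, grid)
    nuc_vol = nuclear_volume(phi0, grid)

    h_phi = interp_h(state.phi)
    h_psi = interp_h(state.psi)
    chi = h_phi.sum(axis=0)
    area = grid.cell_area
    V = h_phi.sum(axis=(1, 2)) * area
    v = (h_phi * h_psi).sum(axis=(1, 2)) * area
    a_scal, c_lin, d_off = _coefficients(V, v, state.t, params, sched, nuc_vol)
    new_phi, new_psi = _euler_numpy(state.phi, state.psi, h_phi, h_psi, chi,
                                    h0, lap_h0, grid, params, a_scal, c_lin,
                                    d_off, cfg.dt)
    if not (np.all(np.isfinite(new_phi)) and np.all(np.isfinite(new_psi))):
        raise RuntimeError(
            f"non-finite update at t={state.t:.6g} (dt={cfg.dt:g}); "
            f"V={V}, v={v}")
    return SimulationState(new_phi, new_psi, phi0, state.t + cfg.dt, grid)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TimeSeriesRecord:
    """Per-record diagnostics of a run; convertible to a pandas DataFrame."""

    rows: list = dataclasses.field(default_factory=list)

    def append(self, row: dict) -> None:
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _record_row(state, params, sched, nuc_vol):
    from . import metrics  # local import: metrics is a consumer of model only

    V_arr, v_arr = None, None
    e = total_energy(state, params, sched)
    h_phi = interp_h(state.phi)
    h_psi = interp_h(state.psi)
    area = state.grid.cell_area
    V_arr = h_phi.sum(axis=(1, 2)) * area
    v_arr = (h_phi * h_psi).sum(axis=(1, 2)) * area
    band = metrics.interface_width(params.eps_psi_sq)
    try:
        contact = metrics.contact_fraction(state.psi, state.phi0, band,
                                           state.grid)
    except ValueError:      # no envelope in the domain (idealized setups)
        contact = float("nan")
    row = {"t": state.t}
    for m in range(state.n_chrom):
        row[f"V_{m + 1}"] = float(V_arr[m])
    for m in range(state.n_chrom):
        row[f"v_{m + 1}"] = float(v_arr[m])
    row.update(E0=e.e0, E1=e.e1, E2=e.e2, E3=e.e3, E=e.total,
               nClusters=metrics.count_hetero_clusters(state.psi),
               contactFraction=contact,
               nuclearVolume=nuc_vol,
               phiMin=float(state.phi.min()), phiMax=float(state.phi.max()),
               psiMin=float(state.psi.min()), psiMax=float(state.psi.max()))
    return row


def run(state: SimulationState, params: ModelParams, sched: ConversionSchedule,
        geom: NucleusGeometry, cfg: SolverConfig,
        callbacks=None) -> tuple[TimeSeriesRecord, SimulationState]:
    """Integrate to ``cfg.t_end``, recording diagnostics every
    ``cfg.record_every`` steps (plus the initial and final states).

    Deterministic given configuration and initial state.  Returns the record
    and the final state.  Aborts with ``RuntimeError`` on non-finite values
    and logs a warning when fields leave the monitored [-0.05, 1.05] band.
    """
    check_stability(cfg, params)
    grid = state.grid
    use_numba = cfg.backend == "numba" or (cfg.backend == "auto"
                                           and _kernels.HAVE_NUMBA)
    if cfg.backend == "numba" and not _kernels.HAVE_NUMBA:
        raise ConfigurationError("numba backend requested but numba is unavailable")

    n_steps = max(0, int(round((cfg.t_end - state.t) / cfg.dt)))
    phi = np.ascontiguousarray(state.phi, dtype=float)
    psi = np.ascontiguousarray(state.psi, dtype=float)
    out_phi = np.empty_like(phi)
    out_psi = np.empty_like(psi)
    h_phi = np.empty_like(phi)
    h_psi = np.empty_like(psi)
    chi = np.empty_like(psi)
    t = state.t
    area = grid.cell_area
    inv_dx2 = 1.0 / grid.dx ** 2
    inv_dy2 = 1.0 / grid.dy ** 2

    axes = None
    phi0 = state.phi0
    h0 = lap_h0 = None
    nuc_vol = np.nan
    bound_violations = 0
    record = TimeSeriesRecord()
    callbacks = callbacks or []

    def refresh_geometry(t_now):
        # the provided phi0 is trusted for static geometries; otherwise the
        # field is rebuilt whenever the scheduled semi-axes change
        nonlocal axes, phi0, h0, lap_h0, nuc_vol
        ax_ay = geometry_at(geom, t_now)
        if axes is None:
            axes = ax_ay
            if not geom.static:
                phi0 = make_phi0(geom, t_now, grid)
        elif ax_ay != axes:
            axes = ax_ay
            phi0 = make_phi0(geom, t_now, grid)
        elif h0 is not None:
            return
        h0 = interp_h(phi0)
        lap_h0 = laplacian(h0, grid)
        nuc_vol = nuclear_volume(phi0, grid)

    def snapshot(t_now):
        return SimulationState(phi.copy(), psi.copy(), phi0.copy(),
                               t_now, grid)

    def do_record(t_now):
        nonlocal bound_violations
        st = snapshot(t_now)
        row = _record_row(st, params, sched, nuc_vol)
        if not (BOUND_LO <= row["phiMin"] and row["phiMax"] <= BOUND_HI
                and BOUND_LO <= row["psiMin"] and row["psiMax"] <= BOUND_HI):
            bound_violations += 1
        record.append(row)
        for cb in callbacks:
            cb(st, row)

    refresh_geometry(t)
    do_record(t)
    for k in range(n_steps):
        refresh_geometry(t)
        if use_numba:
            V, v = _kernels.collect(phi, psi, h_phi, h_psi, chi)
            V = V * area
            v = v * area
            a_scal, c_lin, d_off = _coefficients(V, v, t, params, sched, nuc_vol)
            _kernels.euler_update(
                phi, psi, h_phi, h_psi, chi, h0, lap_h0, out_phi, out_psi,
                cfg.dt * params.mobility_phi, cfg.dt * params.mobility_psi,
                params.eps_phi_sq, params.eps_psi_sq,
                a_scal, c_lin, d_off, c_lin,
                30.0 * params.beta0, 30.0 * params.beta_phi,
                30.0 * params.beta_psi, 30.0 * params.gamma,
                inv_dx2, inv_dy2)
        else:
            np.copyto(h_phi, interp_h(phi))
            np.copyto(h_psi, interp_h(psi))
            np.copyto(chi, h_phi.sum(axis=0))
            V = h_phi.sum(axis=(1, 2)) * area
            v = (h_phi * h_psi).sum(axis=(1, 2)) * area
            a_scal, c_lin, d_off = _coefficients(V, v, t, params, sched, nuc_vol)
            new_phi, new_psi = _euler_numpy(phi, psi, h_phi, h_psi, chi, h0,
                                            lap_h0, grid, params, a_scal,
                                            c_lin, d_off, cfg.dt)
            np.copyto(out_phi, new_phi)
            np.copyto(out_psi, new_psi)
        if not np.all(np.isfinite(V)):
            raise RuntimeError(
                f"non-finite field values at step {k}, t={t:.6g}; "
                f"phi range [{np.nanmin(phi):.3g}, {np.nanmax(phi):.3g}]")
        phi, out_phi = out_phi, phi
        psi, out_psi = out_psi, psi
        t = state.t + (k + 1) * cfg.dt
        if (k + 1) % cfg.record_every == 0 and k + 1 < n_steps:
            do_record(t)
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(psi))):
        raise RuntimeError(f"non-finite field values at t={t:.6g}")
    if n_steps > 0:
        refresh_geometry(t)
        do_record(t)
    if bound_violations:
        logger.warning(
            "fields left the monitored [%g, %g] band in %d of %d records",
            BOUND_LO, BOUND_HI, bound_violations, len(record.rows))
    return record, snapshot(t)
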