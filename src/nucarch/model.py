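"""Algebra of the multi-phase-field chromatin model.

The nucleus interior holds ``N`` chromosome-territory fields ``phi_m`` and one
heterochromatin field ``psi``, all taking values near 0 (absent) or 1
(present).  Their dynamics is the L2 gradient flow of an energy

    E = E0 + E1 + E2 + E3

with E0 the diffuse-interface (gradient + double-well) energy, E1 the
territory restrictions (nuclear confinement S1, heterochromatin confinement
S2, territory exclusion S3), E2 the volume constraints (full nuclear
occupancy R1, chromosome volume targets R2, heterochromatin volume targets
R3) and E3 an envelope-heterochromatin affinity modelling LBR / lamin A
tethering.  This module houses the interpolation and double-well functions,
volume integrals, conversion schedules, the reaction terms ``A_m`` and ``B``
for the conventional and inverted regimes, and a diagnostic energy
evaluation.  Everything here is grid-agnostic algebra; time stepping lives in
:mod:`nucarch.solver`.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .solver import SimulationState

REGIME_CONVENTIONAL = "conventional"
REGIME_INVERTED = "inverted"

VARIANT_SIGMOID = "sigmoid"
VARIANT_SATURATING = "saturating"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelParams:
    """Dimensionless energy and gradient coefficients.

    Attributes
    ----------
    alpha0 : float
        Full-occupancy (R1) coefficient: penalises the gap between the
        nuclear volume and the summed chromosome volumes.
    alpha_V : float
        Chromosome-volume (R2) coefficient.
    alpha_v : float
        Heterochromatin-volume (R3) coefficient.
    beta0 : float
        Nuclear-confinement (S1) coefficient keeping territories inside the
        nucleus.
    beta_phi : float
        Territory-exclusion (S3) coefficient separating chromosomes.
    beta_psi : float
        Heterochromatin-confinement (S2) coefficient keeping heterochromatin
        inside chromosome territories.
    gamma : float
        Envelope-heterochromatin affinity; ``gamma > 0`` models LBR / lamin A
        tethering of peripheral heterochromatin, ``gamma = 0`` their absence.
    eps_phi_sq, eps_psi_sq : float
        Squared gradient coefficients of the territory and heterochromatin
        fields; they set the diffuse-interface (intermingling) widths.
    mobility_phi, mobility_psi, mobility_nucleus : float
        Per-field positive mobility multipliers (default 1).  The nucleus
        field is prescribed, so its multiplier is never used by the dynamics;
        it is kept so scenario tables can be transcribed verbatim.
    n_chrom : int
        Number of chromosome fields N.
    """

    alpha0: float = 25 / 6
    alpha_V: float = 10 / 6
    alpha_v: float = 20 / 3
    beta0: float = 5 / 3
    beta_phi: float = 1.0
    beta_psi: float = 2 / 3
    gamma: float = 0.0
    eps_phi_sq: float = 2e-4
    eps_psi_sq: float = 6e-4
    mobility_phi: float = 1.0
    mobility_psi: float = 1.0
    mobility_nucleus: float = 1.0
    n_chrom: int = 8

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha_V", "alpha_v", "beta0", "beta_phi",
                     "beta_psi", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.eps_phi_sq <= 0 or self.eps_psi_sq <= 0:
            raise ValueError("gradient coefficients eps_phi_sq/eps_psi_sq must be > 0")
        for name in ("mobility_phi", "mobility_psi", "mobility_nucleus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")


@dataclasses.dataclass
class ConversionSchedule:
    """Target volumes and heterochromatin conversion schedule.

    In the *conventional* regime the targets are constants: ``V_bar[m]`` for
    chromosome volume and ``v_bar[m]`` for heterochromatin volume.  In the
    *inverted* regime the chromosome target contracts to ``r * V_bar[m]`` and
    the heterochromatin target tracks ``rho_m(t) * V_m(t)`` where the
    conversion fraction ``rho_m`` rises monotonically from ``rho0[m]`` toward
    ``rho0[m] + rho_bar[m]`` following either the sigmoid

        rho_m(t) = rho_m(0) + rho_bar_m * t / (t + alpha1 * exp(-alpha2*(t - t_star)))

    (``variant="sigmoid"``) or the saturating form

        rho_m(t) = rho_m(0) + rho_bar_m * t / (tau + t)

    (``variant="saturating"``, default ``tau = 10``).
    """

    regime: str = REGIME_CONVENTIONAL
    V_bar: np.ndarray | None = None
    v_bar: np.ndarray | None = None
    r: float = 1.0
    rho0: np.ndarray | None = None
    rho_bar: np.ndarray | None = None
    alpha1: np.ndarray | None = None
    alpha2: np.ndarray | None = None
    t_star: np.ndarray | None = None
    variant: str = VARIANT_SIGMOID
    tau: float = 10.0

    def __post_init__(self) -> None:
        if self.regime not in (REGIME_CONVENTIONAL, REGIME_INVERTED):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.variant not in (VARIANT_SIGMOID, VARIANT_SATURATING):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("V_bar", "v_bar", "rho0", "rho_bar", "alpha1", "alpha2",
                     "t_star"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, np.atleast_1d(np.asarray(val, dtype=float)))
        if self.V_bar is not None and np.any(self.V_bar <= 0):
            raise ValueError("target volumes V_bar must be > 0")
        if not 0 < self.r <= 1:
            raise ValueError(f"contraction ratio r must lie in (0, 1], got {self.r}")
        if self.regime == REGIME_CONVENTIONAL:
            if self.v_bar is not None and self.V_bar is not None \
                    and np.any(self.v_bar > self.V_bar):
                raise ValueError("heterochromatin targets v_bar must not exceed V_bar")
        else:
            if self.rho0 is None or self.rho_bar is None:
                raise ValueError("inverted regime requires rho0 and rho_bar")
            if np.any(self.rho0 < 0) or np.any(self.rho0 + self.rho_bar > 1 + 1e-12):
                raise ValueError("need 0 <= rho0[m] and rho0[m] + rho_bar[m] <= 1")


# ---------------------------------------------------------------------------
# interpolation / double-well
# ---------------------------------------------------------------------------

def interp_h(u):
    """Occupancy interpolation h(u) = u^3 (10 - 15u + 6u^2).

    Maps a phase-field to an effective occupancy with h(0)=0, h(1)=1 and flat
    derivatives at both wells, so bulk regions contribute 0 or 1 exactly.
    """
    u = np.asarray(u, dtype=float)
    return u * u * u * (10.0 + u * (-15.0 + 6.0 * u))


def interp_h_prime(u):
    """h'(u) = 30 u^2 (1-u)^2."""
    u = np.asarray(u, dtype=float)
    return 30.0 * u * u * (1.0 - u) * (1.0 - u)


def doublewell_g(u):
    """Double-well potential g(u) = u^2 (1-u)^2 / 4.

    Chosen so that -g'(u) = u(1-u)(u - 1/2), the bistable reaction kernel of
    the evolution equations; minima of value 0 at u = 0 and u = 1.
    """
    u = np.asarray(u, dtype=float)
    w = u * (1.0 - u)
    return 0.25 * w * w


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def chi_field(phi: np.ndarray) -> np.ndarray:
    """Total territory occupancy chi = sum_m h(phi_m), shape (ny, nx)."""
    return interp_h(phi).sum(axis=0)


def volumes(state: "SimulationState") -> tuple[np.ndarray, np.ndarray]:
    """Chromosome volumes V_m = ∫ h(phi_m) and heterochromatin volumes
    v_m = ∫ h(phi_m) h(psi), as midpoint Riemann sums.

    Returns ``(V, v)``, each of shape ``(N,)``.  Raises ``ValueError`` on
    non-finite field values.
    """
    if not (np.all(np.isfinite(state.phi)) and np.all(np.isfinite(state.psi))):
        raise ValueError(
            "non-finite field values at t={:.6g}: phi range [{:.3g}, {:.3g}], "
            "psi range [{:.3g}, {:.3g}]".format(
                state.t, np.nanmin(state.phi), np.nanmax(state.phi),
                np.nanmin(state.psi), np.nanmax(state.psi)))
    area = state.grid.cell_area
    h_phi = interp_h(state.phi)
    h_psi = interp_h(state.psi)
    V = h_phi.sum(axis=(1, 2)) * area
    v = (h_phi * h_psi).sum(axis=(1, 2)) * area
    return V, v


# ---------------------------------------------------------------------------
# conversion schedule
# ---------------------------------------------------------------------------

def rho_m(t: float, sched: ConversionSchedule, m: int | None = None):
    """Heterochromatin conversion fraction rho_m(t) (inverted regime).

    Monotone non-decreasing in ``t``; equals ``rho0`` at t=0 and approaches
    ``rho0 + rho_bar`` as t → ∞.  Returns the full ``(N,)`` vector, or a
    scalar when ``m`` is given.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if sched.regime != REGIME_INVERTED:
        raise ValueError("rho_m is defined for the inverted regime only")
    rho0 = sched.rho0
    rho_bar = sched.rho_bar
    if sched.variant == VARIANT_SIGMOID:
        denom = t + sched.alpha1 * np.exp(-sched.alpha2 * (t - sched.t_star))
        out = rho0 + rho_bar * t / denom
    else:
        out = rho0 + rho_bar * t / (sched.tau + t)
    return out if m is None else float(out[m])


def targets_at(t: float, sched: ConversionSchedule, V: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous targets (V_target, v_target, rho).

    Conventional regime: constants (V_bar, v_bar, 0).  Inverted regime:
    (r * V_bar, rho_m(t) * V_m(t), rho_m(t)).
    """
    if sched.regime == REGIME_CONVENTIONAL:
        zero = np.zeros_like(sched.V_bar)
        return sched.V_bar, sched.v_bar, zero
    rho = rho_m(t, sched)
    return sched.r * sched.V_bar, rho * V, rho


# ---------------------------------------------------------------------------
# reaction terms
# ---------------------------------------------------------------------------

def _reaction_A_common(m, state, params, chi, h_psi):
    """Terms of A_m shared by both regimes (S1, S3, S2 pressures)."""
    h_phi_m = interp_h(state.phi[m])
    h_phi0 = interp_h(state.phi0)
    return (30.0 * params.beta0 * h_phi0
            + 30.0 * params.beta_phi * (chi - h_phi_m)
            - 30.0 * params.beta_psi * h_psi)


def reaction_A_conventional(m: int, state: "SimulationState",
                            params: ModelParams, sched: ConversionSchedule,
                            chi: np.ndarray, nuc_vol: float) -> np.ndarray:
    """Reaction coefficient field A_m of the conventional-architecture model.

    ``chi`` is sum_m h(phi_m) for the current state and ``nuc_vol`` the
    instantaneous nuclear volume ∫ [1 - h(phi0)].
    """
    if sched.regime != REGIME_CONVENTIONAL:
        raise ValueError("conventional reaction term requires a conventional schedule")
    V, v = volumes(state)
    h_psi = interp_h(state.psi)
    occupancy_gap = nuc_vol - V.sum()          # spatially uniform term
    return (60.0 * params.alpha_V * (V[m] - sched.V_bar[m])
            + 60.0 * params.alpha_v * (v[m] - sched.v_bar[m]) * h_psi
            - 60.0 * params.alpha0 * occupancy_gap
            + _reaction_A_common(m, state, params, chi, h_psi))


def reaction_A_inverted(m: int, state: "SimulationState",
                        params: ModelParams, sched: ConversionSchedule,
                        chi: np.ndarray, nuc_vol: float) -> np.ndarray:
    """Reaction coefficient field A_m of the inverted-architecture model.

    Differs from the conventional form only in the volume-target terms: the
    chromosome target contracts to ``r * V_bar`` and the heterochromatin term
    becomes ``(v_m - rho_m V_m)(h(psi) - rho_m)``, with ``rho_m`` evaluated
    at ``state.t``.
    """
    if sched.regime != REGIME_INVERTED:
        raise ValueError("inverted reaction term requires an inverted schedule")
    V, v = volumes(state)
    rho = rho_m(state.t, sched)
    h_psi = interp_h(state.psi)
    occupancy_gap = nuc_vol - V.sum()
    return (60.0 * params.alpha_V * (V[m] - sched.r * sched.V_bar[m])
            + 60.0 * params.alpha_v * (v[m] - rho[m] * V[m]) * (h_psi - rho[m])
            - 60.0 * params.alpha0 * occupancy_gap
            + _reaction_A_common(m, state, params, chi, h_psi))


def reaction_B(state: "SimulationState", params: ModelParams,
               sched: ConversionSchedule, chi: np.ndarray,
               lap_h0: np.ndarray) -> np.ndarray:
    """Reaction coefficient field B driving the heterochromatin field.

    ``lap_h0`` is the discrete Laplacian of h(phi0) supplied by the solver
    (the affinity term); with ``gamma = 0`` the affinity term is absent.
    """
    V, v = volumes(state)
    _, v_target, _ = targets_at(state.t, sched, V)
    h_phi = interp_h(state.phi)
    dev = (v - v_target)[:, None, None]
    out = 60.0 * params.alpha_v * (dev * h_phi).sum(axis=0)
    out += 30.0 * params.beta_psi * (1.0 - chi)
    if params.gamma != 0.0:
        out -= 30.0 * params.gamma * lap_h0
    return out


# ---------------------------------------------------------------------------
# diagnostic energy
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EnergyBreakdown:
    e0: float   # gradient + double-well
    e1: float   # territory restrictions S1-S3
    e2: float   # volume constraints R1-R3
    e3: float   # envelope affinity
    total: float


def _grad_sq(f: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """|∇f|^2 by central differences with mirrored (zero-flux) edges."""
    p = np.pad(f, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / (2.0 * dx)
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / (2.0 * dy)
    return gx * gx + gy * gy


def _grad(f: np.ndarray, dx: float, dy: float) -> tuple[np.ndarray, np.ndarray]:
    p = np.pad(f, 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / (2.0 * dx)
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / (2.0 * dy)
    return gx, gy


def total_energy(state: "SimulationState", params: ModelParams,
                 sched: ConversionSchedule) -> EnergyBreakdown:
    """Evaluate the energy terms E0..E3 by midpoint Riemann sums.

    Diagnostic only: the dynamics integrates the reaction terms ``A_m`` / ``B``
    directly.  The territory-exclusion sum runs over unordered chromosome
    pairs, which is the convention consistent with the printed A_m.
    """
    grid = state.grid
    area = grid.cell_area
    dx, dy = grid.dx, grid.dy
    h_phi = interp_h(state.phi)
    h_psi = interp_h(state.psi)
    h_phi0 = interp_h(state.phi0)
    chi = h_phi.sum(axis=0)

    e0 = 0.0
    for m in range(state.phi.shape[0]):
        e0 += (0.5 * params.eps_phi_sq * _grad_sq(state.phi[m], dx, dy)
               + doublewell_g(state.phi[m])).sum() * area
    e0 += (0.5 * params.eps_psi_sq * _grad_sq(state.psi, dx, dy)
           + doublewell_g(state.psi)).sum() * area

    # S3 over unordered pairs: sum_{m<n} h_m h_n = (chi^2 - sum h_m^2)/2
    pair_overlap = 0.5 * (chi * chi - (h_phi * h_phi).sum(axis=0))
    e1 = (params.beta0 * (h_phi0[None] * h_phi).sum() * area
          + params.beta_psi * ((1.0 - chi) * h_psi).sum() * area
          + params.beta_phi * pair_overlap.sum() * area)

    V, v = volumes(state)
    V_target, v_target, _ = targets_at(state.t, sched, V)
    nuc_vol = (1.0 - h_phi0).sum() * area
    e2 = (params.alpha0 * (nuc_vol - V.sum()) ** 2
          + params.alpha_V * ((V - V_target) ** 2).sum()
          + params.alpha_v * ((v - v_target) ** 2).sum())

    g0x, g0y = _grad(h_phi0, dx, dy)
    gpx, gpy = _grad(h_psi, dx, dy)
    e3 = params.gamma * (g0x * gpx + g0y * gpy).sum() * area

    return EnergyBreakdown(float(e0), float(e1), float(e2), float(e3),
                           float(e0 + e1 + e2 + e3))
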