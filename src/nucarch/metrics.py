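"""Quantitative readouts of simulated nuclear architectures.

Intermingling (diffuse-interface) widths, heterochromatin cluster counting,
envelope contact, architecture classification, and the sweep-derived phase
boundaries for single-hetero-cluster formation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Grid
from .model import interp_h

LABEL_CONVENTIONAL = "conventional"
LABEL_INVERTED_SINGLE = "inverted_single"
LABEL_INVERTED_MULTI = "inverted_multi"
LABEL_INTERMEDIATE = "intermediate"

#: interface cutoff defining the intermingling band lambda <= u <= 1 - lambda
DEFAULT_LAMBDA = 0.15

#: contact fraction below which an architecture counts as detached from the
#: envelope (inverted)
INVERTED_CONTACT_MAX = 0.1


def interface_width(eps_sq: float, lam: float = DEFAULT_LAMBDA,
                    L: float | None = None) -> float:
    """Intermingling thickness delta = 4 sqrt(2) * eps * artanh(1 - 2 lambda).

    ``eps_sq`` is the squared gradient coefficient of the field; the width is
    the thickness of the band where the equilibrium tanh profile lies between
    ``lam`` and ``1 - lam``.  If ``L`` (a length scale, e.g. 5 um) is given
    the result is returned in dimensional units.
    """
    if not 0 < lam < 0.5:
        raise ValueError(f"lambda must lie in (0, 1/2), got {lam}")
    if eps_sq <= 0:
        raise ValueError(f"eps_sq must be positive, got {eps_sq}")
    delta = 4.0 * np.sqrt(2.0) * np.sqrt(eps_sq) * np.arctanh(1.0 - 2.0 * lam)
    return float(delta * L) if L is not None else float(delta)


def measured_interface_width(profile: np.ndarray, coords: np.ndarray,
                             lam: float = DEFAULT_LAMBDA) -> float:
    """Width of the band ``lam <= profile <= 1 - lam`` of a monotone 1-D
    profile, with the two crossings located by linear interpolation."""
    profile = np.asarray(profile, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if profile[0] > profile[-1]:
        profile = profile[::-1]
        coords = coords[::-1].copy()
    x_lo = np.interp(lam, profile, coords)
    x_hi = np.interp(1.0 - lam, profile, coords)
    return float(abs(x_hi - x_lo))


def count_hetero_clusters(psi: np.ndarray, threshold: float = 0.5,
                          connectivity: int = 4) -> int:
    """Number of connected components of the mask {psi >= threshold}.

    4-neighborhood by default; ``connectivity=8`` includes diagonals.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    _, n = ndimage.label(np.asarray(psi) >= threshold, structure=structure)
    return int(n)


def contact_fraction(psi: np.ndarray, phi0: np.ndarray, band: float,
                     grid: Grid, lam: float = DEFAULT_LAMBDA) -> float:
    """Mean h(psi) over the envelope-adjacent shell.

    The shell is the nucleus interface annulus {lam <= phi0 <= 1 - lam}
    dilated inward (into the nucleus) by ``band``, so it samples the layer of
    the nucleoplasm within one interface scale of the envelope.  The mean is
    weighted by the nucleoplasm indicator 1 - h(phi0) so the exterior tail of
    the diffuse envelope does not dilute it: a nucleus whose envelope layer
    is fully heterochromatic scores ~1 regardless of interface width.
    """
    phi0 = np.asarray(phi0)
    annulus = (phi0 >= lam) & (phi0 <= 1.0 - lam)
    if not annulus.any():
        raise ValueError("empty envelope shell: phi0 has no interface band")
    interior = phi0 < lam
    # distance (in physical units) from each interior cell to the annulus
    dist = ndimage.distance_transform_edt(~annulus, sampling=(grid.dy, grid.dx))
    shell = annulus | (interior & (dist <= band))
    weight = 1.0 - interp_h(phi0[shell])
    return float((interp_h(np.asarray(psi)[shell]) * weight).sum()
                 / weight.sum())


@dataclasses.dataclass
class ArchitectureReport:
    """Summary of a final (or intermediate) simulated state."""

    n_clusters: int
    contact_fraction: float
    label: str
    delta_phi: float
    delta_psi: float
    radial_profile: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"nClusters": self.n_clusters,
                "contactFraction": self.contact_fraction,
                "label": self.label,
                "deltaPhi": self.delta_phi,
                "deltaPsi": self.delta_psi}


def classify(psi: np.ndarray, phi0: np.ndarray, grid: Grid,
             eps_phi_sq: float, eps_psi_sq: float,
             threshold: float = 0.5, connectivity: int = 4,
             band: float | None = None,
             radial_bins: int = 20) -> ArchitectureReport:
    """Classify a state as conventional / inverted_single / inverted_multi /
    intermediate.

    A state is *inverted* when heterochromatin has detached from the envelope
    (contact fraction < 0.1), single vs multi by the cluster count; it is
    *conventional* when the envelope shell is at least half as
    heterochromatin-rich as the nucleus on average (contact fraction >= 0.5 x
    heterochromatin area share); anything else is intermediate.
    """
    if band is None:
        band = interface_width(eps_psi_sq)
    n = count_hetero_clusters(psi, threshold, connectivity)
    cf = contact_fraction(psi, phi0, band, grid)
    interior = np.asarray(phi0) < 0.5
    hetero_share = float(interp_h(np.asarray(psi))[interior].mean()) \
        if interior.any() else 0.0
    if cf < INVERTED_CONTACT_MAX and n == 1:
        label = LABEL_INVERTED_SINGLE
    elif cf < INVERTED_CONTACT_MAX and n > 1:
        label = LABEL_INVERTED_MULTI
    elif cf >= 0.5 * hetero_share:
        label = LABEL_CONVENTIONAL
    else:
        label = LABEL_INTERMEDIATE
    profile = radial_psi_profile(psi, phi0, grid, radial_bins)
    return ArchitectureReport(n, cf, label,
                              interface_width(eps_phi_sq),
                              interface_width(eps_psi_sq), profile)


def radial_psi_profile(psi: np.ndarray, phi0: np.ndarray, grid: Grid,
                       nbins: int = 20) -> np.ndarray:
    """Mean psi versus normalized nuclear radius.

    The radial coordinate is the distance from the nucleus interface scaled
    into [0, 1] (0 = nucleus center, 1 = envelope), computed from phi0 alone
    so the profile works for any nuclear shape.  Returns shape ``(nbins, 2)``
    with columns (bin center, mean psi); empty bins hold NaN.
    """
    phi0 = np.asarray(phi0)
    interior = phi0 < 0.5
    if not interior.any():
        return np.column_stack([(np.arange(nbins) + 0.5) / nbins,
                                np.full(nbins, np.nan)])
    depth = ndimage.distance_transform_edt(interior, sampling=(grid.dy, grid.dx))
    r = 1.0 - depth / depth.max()
    means = np.full(nbins, np.nan)
    edges = np.linspace(0.0, 1.0, nbins + 1)
    vals = np.asarray(psi)[interior]
    rr = r[interior]
    for k in range(nbins):
        sel = (rr >= edges[k]) & (rr < edges[k + 1] if k < nbins - 1
                                  else rr <= edges[k + 1])
        if sel.any():
            means[k] = vals[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return np.column_stack([centers, means])


def phase_boundary(sweep_results: pd.DataFrame, axis: str = "delta_psi"
                   ) -> pd.DataFrame:
    """Single-hetero-cluster formation boundary from labeled sweep runs.

    ``sweep_results`` needs columns ``nucleus_size``, ``delta_phi`` or
    ``delta_psi`` (whichever ``axis`` names) and ``label``.  For each nuclear
    size the boundary is the minimal ``delta_psi`` (resp. maximal
    ``delta_phi``) whose run ended ``inverted_single``; sizes with no
    successful run get NaN and ``defined=False``.  Non-monotone sweeps
    (successes not forming one run along the axis) are flagged raw via
    ``monotone=False``.
    """
    if axis not in ("delta_phi", "delta_psi"):
        raise ValueError("axis must be 'delta_phi' or 'delta_psi'")
    rows = []
    for size, grp in sweep_results.groupby("nucleus_size"):
        grp = grp.sort_values(axis)
        ok = (grp["label"] == LABEL_INVERTED_SINGLE).to_numpy()
        if not ok.any():
            rows.append({"nucleus_size": size, "boundary": np.nan,
                         "defined": False, "monotone": True})
            continue
        idx = np.flatnonzero(ok)
        monotone = bool(np.all(np.diff(idx) == 1))
        if axis == "delta_psi":
            boundary = float(grp[axis].to_numpy()[idx[0]])
        else:
            boundary = float(grp[axis].to_numpy()[idx[-1]])
        rows.append({"nucleus_size": size, "boundary": boundary,
                     "defined": True, "monotone": monotone})
    return pd.DataFrame(rows)
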