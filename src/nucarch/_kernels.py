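"""Numba-accelerated inner loops of the explicit solver.

Importing this module never fails: when numba is unavailable the jitted
callables are replaced by ``None`` and the solver falls back to its numpy
path.  Both paths implement the identical arithmetic (same 5-point mirrored
Laplacian, same reaction evaluation) and are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    njit = None
    HAVE_NUMBA = False


def _collect_py(phi, psi, h_phi, h_psi, chi):
    """Fill h(phi), h(psi), chi in place; return raw (unweighted) V, v sums."""
    n, ny, nx = phi.shape
    V = np.zeros(n)
    v = np.zeros(n)
    for j in range(ny):
        for i in range(nx):
            u = psi[j, i]
            hp = u * u * u * (10.0 + u * (-15.0 + 6.0 * u))
            h_psi[j, i] = hp
            c = 0.0
            for m in range(n):
                u = phi[m, j, i]
                hm = u * u * u * (10.0 + u * (-15.0 + 6.0 * u))
                h_phi[m, j, i] = hm
                c += hm
                V[m] += hm
                v[m] += hm * hp
            chi[j, i] = c
    return V, v


def _euler_py(phi, psi, h_phi, h_psi, chi, h0, lap_h0, out_phi, out_psi,
              dt_phi, dt_psi, eps_phi_sq, eps_psi_sq,
              a_scal, c_lin, d_off, e_lin,
              beta0_30, beta_phi_30, beta_psi_30, gamma_30,
              inv_dx2, inv_dy2):
    """One forward-Euler update of all fields (mirror boundaries)."""
    n, ny, nx = phi.shape
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            hps = h_psi[j, i]
            ch = chi[j, i]
            base = beta0_30 * h0[j, i] - beta_psi_30 * hps
            for m in range(n):
                u = phi[m, j, i]
                lap = ((phi[m, j, im] + phi[m, j, ip] - 2.0 * u) * inv_dx2
                       + (phi[m, jm, i] + phi[m, jp, i] - 2.0 * u) * inv_dy2)
                A = (a_scal[m] + c_lin[m] * (hps - d_off[m])
                     + beta_phi_30 * (ch - h_phi[m, j, i]) + base)
                w = u * (1.0 - u)
                out_phi[m, j, i] = u + dt_phi * (
                    eps_phi_sq * lap + w * (u - 0.5 - A * w))
            u = psi[j, i]
            lap = ((psi[j, im] + psi[j, ip] - 2.0 * u) * inv_dx2
                   + (psi[jm, i] + psi[jp, i] - 2.0 * u) * inv_dy2)
            B = beta_psi_30 * (1.0 - ch) - gamma_30 * lap_h0[j, i]
            for m in range(n):
                B += e_lin[m] * h_phi[m, j, i]
            w = u * (1.0 - u)
            out_psi[j, i] = u + dt_psi * (
                eps_psi_sq * lap + w * (u - 0.5 - B * w))


if HAVE_NUMBA:
    collect = njit(cache=True)(_collect_py)
    euler_update = njit(cache=True)(_euler_py)
else:  # pragma: no cover
    collect = None
    euler_update = None
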