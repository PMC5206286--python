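"""Non-dimensionalization of the model.

The simulation runs in dimensionless units; the physical scales are the
nuclear length scale L = 5 um (chosen so the 1.2 x 1.8 domain spans
6 um x 9 um around the P0 rod-cell nucleus) and the time scale T = 5 h
(matched to the observed reorganization chronology).  The field mobility is
mu = 1/T, and a squared gradient coefficient eps^2 (dimensionless) maps to
the dimensional eps^2 L^2 (um^2); the product mu * eps^2 L^2 acts as the
chromatin diffusion coefficient (um^2/h).
"""

LENGTH_SCALE_UM = 5.0     # L
TIME_SCALE_H = 5.0        # T


def mobility_per_hour(time_scale_h: float = TIME_SCALE_H) -> float:
    """mu = 1/T in 1/h."""
    return 1.0 / time_scale_h


def eps_sq_to_um2(eps_sq: float, length_scale_um: float = LENGTH_SCALE_UM
                  ) -> float:
    """Dimensional squared gradient coefficient eps^2 L^2 in um^2."""
    return eps_sq * length_scale_um ** 2


def diffusion_um2_per_hour(eps_sq: float,
                           length_scale_um: float = LENGTH_SCALE_UM,
                           time_scale_h: float = TIME_SCALE_H) -> float:
    """Effective diffusion coefficient mu * eps^2 L^2 in um^2/h."""
    return mobility_per_hour(time_scale_h) * eps_sq_to_um2(eps_sq,
                                                           length_scale_um)
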