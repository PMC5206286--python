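import numpy as np
import pytest

from nucarch import (Grid, ModelParams, ConversionSchedule, NucleusGeometry,
                     SimulationState, make_phi0)


@pytest.fixture
def small_grid():
    return Grid(nx=40, ny=40, Lx=1.0, Ly=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_random_field(grid, rng, lo=0.0, hi=1.0, sigma=3.0):
    """A smooth random field in [lo, hi] (gaussian-filtered white noise)."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.random(grid.shape), sigma, mode="nearest")
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + (hi - lo) * f


@pytest.fixture
def random_state(small_grid, rng):
    """A small random two-chromosome state inside a circular nucleus."""
    geom = NucleusGeometry(axis_x0=0.3, axis_y0=0.3, axis_x1=0.3,
                           axis_y1=0.3, eps0=4.5e-4)
    phi0 = make_phi0(geom, 0.0, small_grid)
    interior = 1.0 - phi0
    phi = np.stack([
        smooth_random_field(small_grid, rng, 0.0, 0.9) * interior,
        smooth_random_field(small_grid, rng, 0.0, 0.9) * interior,
    ])
    psi = smooth_random_field(small_grid, rng, 0.0, 0.8) * interior
    state = SimulationState(phi, psi, phi0, 0.0, small_grid)
    return state, geom


def conventional_sched(state):
    """Conventional schedule with targets matching the state's volumes."""
    from nucarch import volumes

    V, v = volumes(state)
    return ConversionSchedule(regime="conventional", V_bar=V.copy(),
                              v_bar=v.copy())


@pytest.fixture
def two_chrom_params():
    return ModelParams(n_chrom=2, eps_phi_sq=4e-4, eps_psi_sq=4e-4)
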