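"""Interpolation/double-well algebra, volumes, conversion schedules,
reaction terms and the diagnostic energy."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucarch import (ConversionSchedule, Grid, ModelParams, SimulationState,
                     doublewell_g, interp_h, reaction_A_conventional,
                     reaction_A_inverted, reaction_B, rho_m, total_energy,
                     volumes)
from nucarch.model import interp_h_prime, targets_at

from conftest import conventional_sched


class TestInterpolation:
    @pytest.mark.parametrize("u, expected", [
        (0.0, 0.0), (1.0, 1.0), (0.5, 0.5), (0.2, 0.05792),
    ])
    def test_values(self, u, expected):
        assert interp_h(u) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_partition_symmetry(self, u):
        # h(u) + h(1-u) = 1: two abutting phases interpolate to full occupancy
        assert interp_h(u) + interp_h(1.0 - u) == pytest.approx(1.0, abs=1e-12)

    def test_partition_symmetry_grid(self):
        u = np.linspace(0.0, 1.0, 1000)
        np.testing.assert_allclose(interp_h(u) + interp_h(1.0 - u), 1.0,
                                   atol=1e-12)

    def test_monotone_with_flat_wells(self):
        u = np.linspace(0.0, 1.0, 501)
        assert np.all(np.diff(interp_h(u)) >= 0)
        assert interp_h_prime(0.0) == 0 and interp_h_prime(1.0) == 0

    @pytest.mark.parametrize("u, expected", [
        (0.0, 0.0), (1.0, 0.0), (0.5, 0.015625),
    ])
    def test_doublewell(self, u, expected):
        assert doublewell_g(u) == pytest.approx(expected, abs=1e-14)

    def test_doublewell_gradient_matches_reaction_kernel(self):
        # -g'(u) = u(1-u)(u-1/2) ties the well to the printed kernel
        u = np.linspace(-0.2, 1.2, 201)
        du = 1e-7
        num = -(doublewell_g(u + du) - doublewell_g(u - du)) / (2 * du)
        np.testing.assert_allclose(num, u * (1 - u) * (u - 0.5), atol=1e-7)


class TestVolumes:
    def test_sharp_region(self):
        grid = Grid(10, 10, 1.0, 1.0)
        phi = np.zeros((1, 10, 10))
        phi[0, :5, :] = 1.0               # half the unit square
        state = SimulationState(phi, np.zeros((10, 10)), np.zeros((10, 10)),
                                0.0, grid)
        V, v = volumes(state)
        assert V[0] == pytest.approx(0.5)
        assert v[0] == 0.0                # psi == 0 everywhere

    def test_uniform_half(self):
        grid = Grid(8, 8, 1.0, 1.0)
        phi = np.full((1, 8, 8), 0.5)
        psi = np.full((8, 8), 0.5)
        state = SimulationState(phi, psi, np.zeros((8, 8)), 0.0, grid)
        V, v = volumes(state)
        assert V[0] == pytest.approx(0.5)
        assert v[0] == pytest.approx(0.25)

    def test_nonfinite_rejected(self):
        grid = Grid(4, 4, 1.0, 1.0)
        phi = np.zeros((1, 4, 4))
        phi[0, 0, 0] = np.nan
        state = SimulationState(phi, np.zeros((4, 4)), np.zeros((4, 4)),
                                0.0, grid)
        with pytest.raises(ValueError, match="non-finite"):
            volumes(state)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounds(self, seed):
        # fields in [0,1] imply 0 <= v_m <= V_m <= area
        rng = np.random.default_rng(seed)
        grid = Grid(12, 12, 1.0, 1.0)
        phi = rng.random((2, 12, 12))
        psi = rng.random((12, 12))
        state = SimulationState(phi, psi, np.zeros((12, 12)), 0.0, grid)
        V, v = volumes(state)
        assert np.all(v >= -1e-12) and np.all(v <= V + 1e-12)
        assert np.all(V <= 1.0 + 1e-12)


def _inverted_sched(**kw):
    base = dict(regime="inverted", V_bar=np.ones(1), r=0.6,
                rho0=np.array([0.25]), rho_bar=np.array([0.35]),
                alpha1=np.array([120.0]), alpha2=np.array([0.03]),
                t_star=np.array([120.0]))
    base.update(kw)
    return ConversionSchedule(**base)


class TestConversionSchedule:
    def test_sigmoid_midpoint(self):
        # at t = t* the exponential is 1, the denominator 2 t*, the rise half
        sched = _inverted_sched()
        assert rho_m(120.0, sched, 0) == pytest.approx(0.425, abs=1e-12)

    def test_saturating_value(self):
        sched = _inverted_sched(variant="saturating", rho0=np.array([0.1]),
                                rho_bar=np.array([0.3]))
        assert rho_m(10.0, sched, 0) == pytest.approx(0.25, abs=1e-12)

    def test_endpoints(self):
        sched = _inverted_sched()
        assert rho_m(0.0, sched, 0) == pytest.approx(0.25)
        assert rho_m(1e9, sched, 0) == pytest.approx(0.60, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            rho_m(-1.0, _inverted_sched())

    @pytest.mark.parametrize("sched_kw", [
        # printed sigmoid clocks and the saturating variant
        dict(alpha1=np.array([120.0]), t_star=np.array([120.0])),
        dict(alpha1=np.array([150.0]), t_star=np.array([150.0])),
        dict(alpha1=np.array([80.0]), t_star=np.array([80.0])),
        dict(alpha1=np.array([250.0]), t_star=np.array([250.0])),
        dict(variant="saturating"),
    ])
    def test_monotone(self, sched_kw):
        sched = _inverted_sched(**sched_kw)
        t = np.linspace(0.0, 2000.0, 4001)
        vals = np.array([rho_m(tt, sched, 0) for tt in t])
        assert np.all(np.diff(vals) >= -1e-12)

    def test_invariant_validation(self):
        with pytest.raises(ValueError, match="rho0"):
            _inverted_sched(rho0=np.array([0.8]), rho_bar=np.array([0.3]))
        with pytest.raises(ValueError, match="contraction"):
            _inverted_sched(r=0.0)


class TestReactionTerms:
    def _single_cell_state(self, h_targets, psi_val=0.0):
        # one-cell grid whose phi values hit prescribed h() values
        from scipy.optimize import brentq

        grid = Grid(1, 1, 1.0, 1.0)
        phis = [brentq(lambda u, target=target: interp_h(u) - target, 0, 1)
                for target in h_targets]
        phi = np.array(phis).reshape(-1, 1, 1)
        psi = np.full((1, 1), psi_val)
        phi0 = np.zeros((1, 1))
        return SimulationState(phi, psi, phi0, 0.0, grid)

    def test_all_coefficients_zero(self, random_state):
        state, _ = random_state
        params = ModelParams(alpha0=0, alpha_V=0, alpha_v=0, beta0=0,
                             beta_phi=0, beta_psi=0, gamma=0, n_chrom=2)
        sched = conventional_sched(state)
        chi = interp_h(state.phi).sum(axis=0)
        nv = 1.0
        for m in range(2):
            np.testing.assert_array_equal(
                reaction_A_conventional(m, state, params, sched, chi, nv), 0.0)
        np.testing.assert_array_equal(
            reaction_B(state, params, sched, chi, np.zeros_like(chi)), 0.0)

    def test_on_target_volume_term_vanishes(self, random_state):
        state, _ = random_state
        params = ModelParams(alpha0=0, alpha_V=3.0, alpha_v=0, beta0=0,
                             beta_phi=0, beta_psi=0, n_chrom=2)
        sched = conventional_sched(state)   # targets equal current volumes
        chi = interp_h(state.phi).sum(axis=0)
        A = reaction_A_conventional(0, state, params, sched, chi, 1.0)
        np.testing.assert_allclose(A, 0.0, atol=1e-12)

    def test_exclusion_term_hand_value(self):
        # two chromosomes with h=0.5 each, only beta_phi=1 active:
        # A_1 = 30 * (chi - h(phi_1)) = 30 * 0.5 = 15
        state = self._single_cell_state([0.5, 0.5])
        params = ModelParams(alpha0=0, alpha_V=0, alpha_v=0, beta0=0,
                             beta_phi=1.0, beta_psi=0, n_chrom=2)
        sched = ConversionSchedule(regime="conventional",
                                   V_bar=np.array([1.0, 1.0]),
                                   v_bar=np.array([0.0, 0.0]))
        chi = interp_h(state.phi).sum(axis=0)
        A = reaction_A_conventional(0, state, params, sched, chi, 1.0)
        assert A[0, 0] == pytest.approx(15.0, abs=1e-12)

    def test_regime_mismatch_rejected(self, random_state):
        state, _ = random_state
        params = ModelParams(n_chrom=2)
        conv = conventional_sched(state)
        chi = interp_h(state.phi).sum(axis=0)
        with pytest.raises(ValueError, match="inverted"):
            reaction_A_inverted(0, state, params, conv, chi, 1.0)
        inv = _inverted_sched(V_bar=np.ones(2), rho0=np.full(2, 0.2),
                              rho_bar=np.full(2, 0.3),
                              alpha1=np.full(2, 120.0),
                              alpha2=np.full(2, 0.03),
                              t_star=np.full(2, 120.0))
        with pytest.raises(ValueError, match="conventional"):
            reaction_A_conventional(0, state, params, inv, chi, 1.0)

    def test_inverted_hetero_term_vanishes_on_target(self, random_state):
        # v_m = rho_m V_m makes the alpha_v factor vanish identically
        state, _ = random_state
        V, v = volumes(state)
        rho0 = v / V
        sched = _inverted_sched(V_bar=V.copy(), r=1.0, rho0=rho0,
                                rho_bar=np.zeros(2),
                                alpha1=np.full(2, 120.0),
                                alpha2=np.full(2, 0.03),
                                t_star=np.full(2, 120.0))
        params = ModelParams(alpha0=0, alpha_V=0, alpha_v=5.0, beta0=0,
                             beta_phi=0, beta_psi=0, n_chrom=2)
        chi = interp_h(state.phi).sum(axis=0)
        A = reaction_A_inverted(0, state, params, sched, chi, 1.0)
        np.testing.assert_allclose(A, 0.0, atol=1e-10)

    def test_conventional_inverted_consistency(self, random_state):
        # with r=1 and rho frozen at v_bar/V_bar the alpha_V terms coincide
        state, _ = random_state
        V, v = volumes(state)
        params = ModelParams(alpha0=0, alpha_V=2.0, alpha_v=0, beta0=0,
                             beta_phi=0, beta_psi=0, n_chrom=2)
        conv = ConversionSchedule(regime="conventional", V_bar=0.9 * V,
                                  v_bar=0.5 * v)
        inv = _inverted_sched(V_bar=0.9 * V, r=1.0, rho0=v / V,
                              rho_bar=np.zeros(2),
                              alpha1=np.full(2, 120.0),
                              alpha2=np.full(2, 0.03),
                              t_star=np.full(2, 120.0))
        chi = interp_h(state.phi).sum(axis=0)
        for m in range(2):
            np.testing.assert_allclose(
                reaction_A_conventional(m, state, params, conv, chi, 1.0),
                reaction_A_inverted(m, state, params, inv, chi, 1.0),
                atol=1e-12)

    def test_B_affinity_absent_for_uniform_phi0(self, random_state):
        state, _ = random_state
        params = ModelParams(alpha0=0, alpha_V=0, alpha_v=0, beta0=0,
                             beta_phi=0, beta_psi=0, gamma=5.0, n_chrom=2)
        sched = conventional_sched(state)
        chi = interp_h(state.phi).sum(axis=0)
        # Laplacian of a constant phi0 is identically zero
        B = reaction_B(state, params, sched, chi, np.zeros_like(chi))
        np.testing.assert_array_equal(B, 0.0)

    def test_B_zero_at_full_occupancy_on_target(self, random_state):
        state, _ = random_state
        state = state[0] if isinstance(state, tuple) else state
        params = ModelParams(alpha_v=4.0, beta_psi=2.0, gamma=0.0, n_chrom=2)
        sched = conventional_sched(state)
        chi = np.ones_like(state.psi)        # chi == 1 and v on target
        B = reaction_B(state, params, sched, chi, np.zeros_like(chi))
        np.testing.assert_allclose(B, 0.0, atol=1e-12)


class TestEnergy:
    def test_zero_state(self):
        grid = Grid(8, 8, 1.0, 1.0)
        state = SimulationState(np.zeros((1, 8, 8)), np.zeros((8, 8)),
                                np.ones((8, 8)), 0.0, grid)
        sched = ConversionSchedule(regime="conventional",
                                   V_bar=np.array([1e-9]),
                                   v_bar=np.array([0.0]))
        e = total_energy(state, ModelParams(n_chrom=1), sched)
        assert e.total == pytest.approx(0.0, abs=1e-12)

    def test_uniform_state_reduces_to_doublewell(self):
        grid = Grid(8, 8, 1.0, 1.0)
        u = 0.3
        state = SimulationState(np.full((1, 8, 8), u), np.zeros((8, 8)),
                                np.ones((8, 8)), 0.0, grid)
        params = ModelParams(alpha0=0, alpha_V=0, alpha_v=0, beta0=0,
                             beta_phi=0, beta_psi=0, n_chrom=1)
        sched = ConversionSchedule(regime="conventional",
                                   V_bar=np.array([1.0]),
                                   v_bar=np.array([0.0]))
        e = total_energy(state, params, sched)
        assert e.e0 == pytest.approx(float(doublewell_g(u)), rel=1e-12)
        assert e.e1 == e.e2 == e.e3 == 0.0

    def test_targets_at_conventional_constant(self):
        sched = ConversionSchedule(regime="conventional",
                                   V_bar=np.array([2.0]),
                                   v_bar=np.array([0.5]))
        Vt, vt, rho = targets_at(3.0, sched, np.array([1.7]))
        assert Vt[0] == 2.0 and vt[0] == 0.5 and rho[0] == 0.0

    def test_targets_at_inverted_tracks_volume(self):
        sched = _inverted_sched()
        Vt, vt, rho = targets_at(120.0, sched, np.array([0.8]))
        assert Vt[0] == pytest.approx(0.6)
        assert rho[0] == pytest.approx(0.425)
        assert vt[0] == pytest.approx(0.425 * 0.8)
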