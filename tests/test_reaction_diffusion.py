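"""Reaction kinetics, steady-state spherical profiles and the time-dependent solver."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.constants import Avogadro
from scipy.integrate import solve_ivp

import mesocluster as mc
from mesocluster.errors import InvalidArgumentError
from oracles import fd_oracle


class TestReactionRates:
    def test_zero_at_equilibrium(self):
        k1, k2, n1 = 2e-22, 1.25e5, 1e26
        n2 = k1 * n1**2 / k2
        dn1, dn2 = mc.reaction_rates(n1, n2, k1, k2)
        assert dn1 == pytest.approx(0.0, abs=1e-9 * k1 * n1**2)
        assert dn2 == pytest.approx(0.0, abs=1e-9 * k1 * n1**2)

    def test_pure_formation_without_dimers(self):
        dn1, dn2 = mc.reaction_rates(1e26, 0.0, 2e-22, 1.25e5)
        assert dn2 == pytest.approx(2e-22 * 1e52, rel=1e-14)
        assert dn1 == -2 * dn2

    @given(st.integers(0, 300))
    def test_conservation_is_exact(self, draw):
        rng = np.random.default_rng(draw)
        n1, n2 = rng.uniform(0, 1e27, 2)
        k1, k2 = 10 ** rng.uniform(-25, -20), 10 ** rng.uniform(2, 7)
        dn1, dn2 = mc.reaction_rates(n1, n2, k1, k2)
        assert dn1 + 2 * dn2 == 0.0

    def test_closed_box_relaxes_to_equilibrium(self, rd_params):
        # Stiff 0-D integration from a far-from-equilibrium start: total
        # molecules conserved and endpoint satisfies detailed balance.
        k1, k2 = rd_params.k1, rd_params.k2
        n_tot = rd_params.n1_inf + 2 * rd_params.n2_inf

        def rhs(t, y):
            return mc.reaction_rates(y[0], y[1], k1, k2)

        sol = solve_ivp(rhs, (0, 1e-2), [n_tot, 0.0], method="Radau",
                        rtol=1e-10, atol=1e10)
        n1, n2 = sol.y[:, -1]
        assert n1 + 2 * n2 == pytest.approx(n_tot, rel=1e-9)
        assert k1 * n1**2 == pytest.approx(k2 * n2, rel=1e-6)


class TestUnitPlumbing:
    def test_kd_number_density_conversion(self):
        assert mc.kd_to_number_density(1.147) == pytest.approx(
            1.147 / (Avogadro * 1e3), rel=1e-14
        )
        assert mc.kd_to_number_density(0.0) == 0.0

    def test_molar_density_round_trip(self):
        assert mc.molar_to_number_density(1.0) == pytest.approx(6.02214076e26, rel=1e-8)
        assert mc.number_density_to_molar(mc.molar_to_number_density(0.37)) == pytest.approx(
            0.37, rel=1e-14
        )


class TestDecayRate:
    def test_cluster_scale_value(self):
        assert mc.decay_rate_from_radius(3.2e-11, 1.6e-8) == pytest.approx(1.25e5, rel=1e-12)

    def test_inverse_square_scaling_and_inverse(self):
        base = mc.decay_rate_from_radius(3.2e-11, 1.6e-8)
        assert mc.decay_rate_from_radius(3.2e-11, 4 * 1.6e-8) == pytest.approx(
            base / 16, rel=1e-12
        )
        assert mc.screening_length(3.2e-11, 1.25e5) == pytest.approx(1.6e-8, rel=1e-12)


class TestRDParams:
    def test_equilibrium_invariant_enforced(self):
        with pytest.raises(InvalidArgumentError):
            mc.RDParams(k1=1e-22, k2=1e5, D1=4e-11, D2=3.2e-11,
                        n1_inf=1e26, n2_inf=1e26)

    def test_from_solution_is_equilibrated(self, rd_params):
        assert rd_params.k1 * rd_params.n1_inf**2 == pytest.approx(
            rd_params.k2 * rd_params.n2_inf, rel=1e-9
        )


class TestSteadyProfiles:
    R = 1.6e-8

    def test_zero_contrast_gives_flat_bulk(self, rd_params, radial_grid):
        prof = mc.steady_profiles(rd_params, self.R, 0.0, radial_grid)
        np.testing.assert_allclose(prof.n1, rd_params.n1_inf, rtol=1e-14)
        np.testing.assert_allclose(prof.n2, rd_params.n2_inf, rtol=1e-14)

    def test_cluster_shape(self, rd_params, radial_grid):
        # Dimers enriched inside, monomers depleted inside, both monotone
        # toward bulk, smooth across the cluster boundary.
        prof = mc.steady_profiles(rd_params, self.R, 10.0, radial_grid)
        assert prof.n2[0] > 2 * rd_params.n2_inf
        assert prof.n1[0] < rd_params.n1_inf
        assert np.all(np.diff(prof.n2) <= 1e-12 * rd_params.n2_inf)
        assert np.all(np.diff(prof.n1) >= -1e-12 * rd_params.n1_inf)

    def test_no_discontinuity_at_boundary(self, rd_params):
        # Fine grid bracketing R: consecutive jumps stay O(grid spacing),
        # with no step at the matching radius.
        grid = np.linspace(0.9 * self.R, 1.1 * self.R, 4001)
        prof = mc.steady_profiles(rd_params, self.R, 10.0, grid)
        jumps = np.abs(np.diff(prof.n2))
        scale = prof.n2.max() - prof.n2.min()
        assert jumps.max() < 1e-3 * scale  # ~1/4000 of the local range per step
        # no outlier step where the interior and exterior branches meet: the
        # largest node-to-node change is comparable to the typical slope·h
        assert jumps.max() < 3 * np.median(jumps)

    def test_far_field_and_flux_balance(self, rd_params, radial_grid):
        prof = mc.steady_profiles(rd_params, self.R, 10.0, radial_grid)
        lam = prof.lambda_screen
        at_10lam = np.interp(10 * lam, prof.r, prof.n2)
        assert at_10lam == pytest.approx(rd_params.n2_inf, rel=1e-3)
        fb = (rd_params.D1 * (prof.n1 - rd_params.n1_inf)
              + 2 * rd_params.D2 * (prof.n2 - rd_params.n2_inf))
        assert np.abs(fb).max() < 1e-12 * rd_params.D2 * rd_params.n2_inf

    @pytest.mark.parametrize("contrast", [3.0, 10.0, 35.0])
    def test_qualitative_shape_invariant_across_contrast_sweep(
        self, rd_params, radial_grid, contrast
    ):
        prof = mc.steady_profiles(rd_params, self.R, contrast, radial_grid)
        assert np.all(np.diff(prof.n2) <= 1e-12 * rd_params.n2_inf)
        assert np.all(np.diff(prof.n1) >= -1e-12 * rd_params.n1_inf)
        assert np.all(prof.n1 >= -1e-9 * rd_params.n1_inf)

    def test_matches_finite_difference_oracle(self, rd_params, radial_grid):
        prof = mc.steady_profiles(rd_params, self.R, 10.0, radial_grid)
        u = fd_oracle(rd_params, self.R, prof.core_plateau, radial_grid)
        dn2 = prof.n2 - rd_params.n2_inf
        assert np.abs(u - dn2).max() / np.abs(dn2).max() < 1e-3

    def test_contrast_clipping_warns(self, rd_params, radial_grid, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mesocluster.reaction_diffusion"):
            prof = mc.steady_profiles(rd_params, self.R, 1e4, radial_grid)
        assert "clipped" in caplog.text
        assert prof.n1.min() >= -1e-6 * rd_params.n1_inf

    def test_grid_must_span_cluster(self, rd_params):
        with pytest.raises(InvalidArgumentError):
            mc.steady_profiles(rd_params, 1.6e-8, 5.0, np.geomspace(1e-7, 1e-6, 50))


class TestEvolveRD:
    def test_uniform_equilibrium_is_stationary(self, rd_params, radial_grid):
        n = len(radial_grid)
        ev = mc.evolve_rd(rd_params, np.full(n, rd_params.n1_inf),
                          np.full(n, rd_params.n2_inf), radial_grid, 1e-4)
        assert np.abs(ev.n2 - rd_params.n2_inf).max() <= 1e-9 * rd_params.n2_inf
        assert np.abs(ev.n1 - rd_params.n1_inf).max() <= 1e-9 * rd_params.n1_inf

    def test_closed_box_conserves_total_molecules(self, rd_params, radial_grid):
        lam = mc.screening_length(rd_params.D2, rd_params.k2)
        n = len(radial_grid)
        n2_0 = rd_params.n2_inf * (1 + 0.5 * np.exp(-(((radial_grid - 3 * lam)) / lam) ** 2))
        ev = mc.evolve_rd(rd_params, np.full(n, rd_params.n1_inf), n2_0, radial_grid,
                          2e-4, outer="closed", rtol=1e-10)
        tot = ev.total_molecules()
        assert np.abs(tot - tot[0]).max() < 1e-6 * tot[0]

    def test_relaxes_to_analytic_steady_profile(self, rd_params, radial_grid):
        R = 1.6e-8
        prof = mc.steady_profiles(rd_params, R, 10.0, radial_grid)
        n = len(radial_grid)
        ev = mc.evolve_rd(rd_params, np.full(n, rd_params.n1_inf),
                          np.full(n, rd_params.n2_inf), radial_grid, 3e-4,
                          R_cluster=R, core_plateau=prof.core_plateau, outer="fixed")
        scale = np.sqrt(np.mean((prof.n2 - rd_params.n2_inf) ** 2))
        l2 = np.sqrt(np.mean((ev.n2 - prof.n2) ** 2, axis=1)) / scale
        assert l2[-1] < 0.01
        # distance to the steady state decreases (allowing plateau jitter)
        assert np.all(np.diff(l2) < 1e-6)

    def test_rejects_unknown_boundary(self, rd_params, radial_grid):
        n = len(radial_grid)
        with pytest.raises(InvalidArgumentError):
            mc.evolve_rd(rd_params, np.full(n, rd_params.n1_inf),
                         np.full(n, rd_params.n2_inf), radial_grid, 1e-5,
                         outer="reflecting")
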