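import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prewetbelt import GridGeometry, equilibrium_wells, local_free_energy
from prewetbelt.model.thermo import (
    chemical_potential_field,
    f_prime,
    grand_potential,
    spinodal_tilts,
)

phis = st.floats(min_value=1e-4, max_value=1 - 1e-4)
chis = st.floats(min_value=0.0, max_value=6.0)


class TestFreeEnergy:
    def test_pure_mixing_entropy_at_half(self):
        assert local_free_energy(0.5, chi=0.0) == pytest.approx(np.log(0.5), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(phi=phis, chi=chis)
    def test_symmetry_about_one_half(self, phi, chi):
        assert local_free_energy(phi, chi) == pytest.approx(
            local_free_energy(1 - phi, chi), rel=1e-10, abs=1e-12
        )

    def test_domain_error_outside_unit_interval(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                local_free_energy(bad, chi=3.0)

    def test_tilted_density_has_two_minima_for_chi_2p75(self):
        # oracle: grid search over phi in (0,1), step 1e-4
        chi = 2.75
        phi = np.arange(1e-4, 1.0, 1e-4)
        omega = local_free_energy(phi, chi)  # tilt = 0
        interior = (omega[1:-1] < omega[:-2]) & (omega[1:-1] < omega[2:])
        n_minima = int(interior.sum())
        assert n_minima == 2


class TestEquilibriumWells:
    def test_single_convex_well_at_chi_zero(self):
        wells = equilibrium_wells(chi=0.0, tilt=0.0)
        assert len(wells) == 1
        assert wells[0][0] == pytest.approx(0.5, abs=1e-10)

    def test_symmetric_wells_equal_depth_at_zero_tilt(self):
        wells = equilibrium_wells(chi=2.75, tilt=0.0)
        assert len(wells) == 2
        (p1, w1), (p2, w2) = wells
        assert p1 == pytest.approx(1 - p2, abs=1e-9)
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_dense_well_global_at_large_positive_tilt(self):
        wells = equilibrium_wells(chi=2.75, tilt=0.25)
        assert len(wells) == 2
        assert wells[1][1] < wells[0][1]  # omega_dense < omega_dilute

    def test_wells_match_grid_search_oracle(self):
        chi, tilt = 3.5, 0.2
        phi = np.arange(1e-4, 1.0, 1e-4)
        omega = local_free_energy(phi, chi) - tilt * phi
        interior = np.nonzero(
            (omega[1:-1] < omega[:-2]) & (omega[1:-1] < omega[2:])
        )[0]
        grid_minima = phi[interior + 1]
        wells = equilibrium_wells(chi, tilt)
        assert len(wells) == len(grid_minima)
        for (p, _), pg in zip(wells, grid_minima):
            assert p == pytest.approx(pg, abs=2e-4)

    def test_roots_satisfy_fprime_equals_tilt(self):
        for tilt in (-0.6, 0.0, 0.43):
            for p, _ in equilibrium_wells(3.5, tilt):
                assert f_prime(p, 3.5) == pytest.approx(tilt, abs=1e-9)

    def test_spinodal_tilt_bounds_metastability(self):
        lo_hi = spinodal_tilts(3.5)
        assert lo_hi is not None
        # beyond the dilute spinodal only the dense well survives
        assert len(equilibrium_wells(3.5, lo_hi[0] + 0.05)) == 1
        assert len(equilibrium_wells(3.5, lo_hi[0] - 0.05)) == 2


class TestChemicalPotential:
    def test_homogeneous_half_is_zero(self):
        phi = np.full((16, 24), 0.5)
        eps = np.zeros((16, 24))
        mu = chemical_potential_field(phi, eps, chi=3.1, kappa=2.0)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)

    def test_homogeneous_field_has_no_gradient_term(self):
        phi0, eps0, chi = 0.3, 1.7, 3.5
        phi = np.full((12, 20), phi0)
        eps = np.full((12, 20), eps0)
        mu = chemical_potential_field(phi, eps, chi=chi, kappa=4.0)
        expected = np.log(phi0 / (1 - phi0)) + chi * (1 - 2 * phi0) - eps0
        np.testing.assert_allclose(mu, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            chemical_potential_field(
                np.full((8, 8), 0.5), np.zeros((8, 9)), chi=3.0, kappa=1.0
            )

    def test_matches_discrete_functional_derivative(self):
        # oracle: central finite difference of the grand potential under
        # a one-pixel perturbation; mu - mu_bulk must equal dG/dphi / h^2
        rng = np.random.default_rng(7)
        chi, kappa, mu_bulk, h = 3.5, 4.0, -3.0, 1.0
        n = 16
        base = 0.3 + 0.1 * np.sin(np.arange(n) / 3.0)
        phi = np.clip(
            base[:, None] + 0.05 * rng.standard_normal((n, n)), 0.05, 0.95
        )
        eps = 2.4 + 0.5 * rng.random((n, n))
        mu = chemical_potential_field(phi, eps, chi=chi, kappa=kappa, spacing=h)
        delta = 3e-5
        for i, j in [(0, 0), (7, 5), (15, 15), (8, 0), (0, 9)]:
            up = phi.copy()
            up[i, j] += delta
            dn = phi.copy()
            dn[i, j] -= delta
            dG = (
                grand_potential(up, eps, chi, kappa, mu_bulk, h)
                - grand_potential(dn, eps, chi, kappa, mu_bulk, h)
            ) / (2 * delta)
            assert mu[i, j] - mu_bulk == pytest.approx(dG / h**2, abs=1e-6)
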