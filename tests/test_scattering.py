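"""Single-scattering physics: Mie spheres, oblique-incidence cylinders,
and the polarization-aware rejection samplers.

The independent oracles are: the Rayleigh closed forms at small size
parameter, a second Mie implementation built directly on scipy's
spherical Bessel functions (upward recurrence, no shared code), and
azimuthal quadrature of the cylinder amplitude series for the energy
balance.
"""

import numpy as np
import pytest
from scipy import special
from scipy.stats import chisquare, kstest

from polarmc.cylinder import (
    cylinder_amplitudes,
    cylinder_coefficients,
    cylinder_efficiencies,
    cylinder_mueller,
)
from polarmc.mie import (
    mie_ab,
    mie_amplitudes,
    mie_cross_section,
    mie_efficiency,
    mueller_from_jones,
    single_scatter_mueller,
)
from polarmc.sampling import sample_cylinder_angles, sample_sphere_angles

X_DERMIS = 0.784  # sphere of radius 0.05 um at 0.533 um in the host
M_REL = 1.45 / 1.33


def mie_ab_reference(x, m):
    """Independent Mie coefficients via scipy spherical Bessels."""
    n_stop = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    n = np.arange(1, n_stop + 1)
    mx = m * x
    jx = special.spherical_jn(n, x)
    jxp = special.spherical_jn(n, x, derivative=True)
    yx = special.spherical_yn(n, x)
    yxp = special.spherical_yn(n, x, derivative=True)
    jm = special.spherical_jn(n, mx)
    jmp = special.spherical_jn(n, mx, derivative=True)
    hx = jx + 1j * yx
    hxp = jxp + 1j * yxp
    # Riccati-Bessel derivatives: [z f(z)]' = f(z) + z f'(z)
    dpsi_x = jx + x * jxp
    dpsi_mx = jm + mx * jmp
    dxi_x = hx + x * hxp
    a = (m**2 * jm * dpsi_x - jx * dpsi_mx) / (m**2 * jm * dxi_x - hx * dpsi_mx)
    b = (jm * dpsi_x - jx * dpsi_mx) / (jm * dxi_x - hx * dpsi_mx)
    return a, b


class TestMieSphere:
    def test_forward_amplitude_degeneracy(self):
        S1, S2 = mie_amplitudes(X_DERMIS, M_REL, 0.0)
        assert S1 == pytest.approx(S2)

    def test_rayleigh_dipole_ratio(self):
        theta = np.linspace(0.02, np.pi - 0.02, 80)
        S1, S2 = mie_amplitudes(0.05, 1.0902, theta)
        np.testing.assert_allclose(S2 / S1, np.cos(theta), atol=1e-3)

    def test_matched_index_no_scattering(self):
        S1, S2 = mie_amplitudes(0.5, 1.0, 0.7)
        assert S1 == 0.0 and S2 == 0.0
        assert mie_efficiency(0.5, 1.0) == 0.0

    def test_qsca_rayleigh_limit(self):
        x, m = 0.1, 1.0902
        rayleigh = 8.0 / 3.0 * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        assert mie_efficiency(x, m) == pytest.approx(rayleigh, rel=0.01)

    @pytest.mark.parametrize("x", [0.3, 1.0, 5.0])
    def test_coefficients_match_independent_series(self, x):
        a, b = mie_ab(x, M_REL)
        a_ref, b_ref = mie_ab_reference(x, M_REL)
        np.testing.assert_allclose(a, a_ref, atol=1e-8)
        np.testing.assert_allclose(b, b_ref, atol=1e-8)

    def test_cross_section_geometry(self):
        sigma, q = mie_cross_section(1.0, M_REL, 0.533, 1.33)
        radius = 0.533 / (2.0 * np.pi * 1.33)
        assert sigma == pytest.approx(q * np.pi * radius**2)

    def test_cross_sections_increase_with_size(self):
        xs = np.linspace(0.05, 1.0, 30)
        qs = [mie_efficiency(x, M_REL) for x in xs]
        assert np.all(np.diff(qs) > 0)

    def test_invalid_size_parameter(self):
        with pytest.raises(ValueError):
            mie_ab(0.0, M_REL)


class TestScatterMueller:
    def test_forward_matrix_is_polarization_free(self):
        M = single_scatter_mueller(X_DERMIS, M_REL, 0.0)
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12 * M[0, 0])
        assert M[2, 2] == pytest.approx(M[0, 0])

    def test_rayleigh_full_polarization_at_right_angle(self):
        M = single_scatter_mueller(0.05, 1.0902, np.pi / 2)
        assert M[0, 1] / M[0, 0] == pytest.approx(-1.0, abs=1e-3)

    def test_block_symmetries_everywhere(self):
        theta = np.linspace(0.0, np.pi, 91)
        M = single_scatter_mueller(X_DERMIS, M_REL, theta)
        np.testing.assert_allclose(M[:, 1, 1], M[:, 0, 0])
        np.testing.assert_allclose(M[:, 3, 3], M[:, 2, 2])
        np.testing.assert_allclose(M[:, 3, 2], -M[:, 2, 3])

    def test_intensity_integral_matches_cross_section(self):
        # quadrature of S11 over the sphere reproduces the series Qsca:
        # integral S11 sin(theta) dtheta dphi = pi x^2 Qsca
        theta = np.linspace(0.0, np.pi, 2001)
        s11 = single_scatter_mueller(X_DERMIS, M_REL, theta)[:, 0, 0]
        integral = 2.0 * np.pi * np.trapezoid(s11 * np.sin(theta), theta)
        expected = np.pi * X_DERMIS**2 * mie_efficiency(X_DERMIS, M_REL)
        assert integral == pytest.approx(expected, rel=1e-6)

    def test_jones_conversion_identity(self):
        np.testing.assert_allclose(mueller_from_jones(np.eye(2)), np.eye(4), atol=1e-12)


class TestCylinder:
    def test_normal_incidence_has_no_cross_polarization(self):
        Theta = np.linspace(0.0, 2.0 * np.pi, 50)
        _, _, T3, T4 = cylinder_amplitudes(X_DERMIS, M_REL, np.pi / 2, Theta)
        assert np.max(np.abs(T3)) < 1e-14
        assert np.max(np.abs(T4)) < 1e-14

    def test_matched_index_no_scattering(self):
        T = cylinder_amplitudes(0.8, 1.0, 1.0, np.array([0.3]))
        assert all(np.allclose(t, 0.0) for t in T)

    @pytest.mark.parametrize("zeta", [np.pi / 2, 1.0, 0.4])
    @pytest.mark.parametrize("x", [X_DERMIS, 2.0])
    def test_energy_balance_quadrature(self, zeta, x):
        # integral of the scattered intensity over the cone azimuth must
        # close against the efficiency series to 0.1%
        Theta = np.linspace(0.0, 2.0 * np.pi, 4001)
        T1, T2, T3, T4 = cylinder_amplitudes(x, M_REL, zeta, Theta)
        qI, qII = cylinder_efficiencies(x, M_REL, zeta)
        intI = np.trapezoid(np.abs(T1) ** 2 + np.abs(T3) ** 2, Theta)
        intII = np.trapezoid(np.abs(T2) ** 2 + np.abs(T4) ** 2, Theta)
        assert intI == pytest.approx(np.pi * x * qI, rel=1e-3)
        assert intII == pytest.approx(np.pi * x * qII, rel=1e-3)

    def test_optical_theorem_at_any_incidence(self):
        # forward amplitude real part ties to the efficiencies (no
        # absorption): Re T_j(0) = x q_j / 2
        for zeta in (np.pi / 2, 1.2, 0.5):
            T1, T2, _, _ = cylinder_amplitudes(X_DERMIS, M_REL, zeta, 0.0)
            qI, qII = cylinder_efficiencies(X_DERMIS, M_REL, zeta)
            assert np.real(T1[0]) == pytest.approx(X_DERMIS * qI / 2, rel=1e-9)
            assert np.real(T2[0]) == pytest.approx(X_DERMIS * qII / 2, rel=1e-9)

    def test_grazing_incidence_rejected(self):
        with pytest.raises(ValueError):
            cylinder_coefficients(0.8, M_REL, 0.0)

    def test_mueller_first_element_positive(self):
        M = cylinder_mueller(X_DERMIS, M_REL, 1.1, np.linspace(0, 2 * np.pi, 30))
        assert np.all(M[:, 0, 0] > 0)


class TestAngleSampling:
    N = 100_000

    def test_unpolarized_phi_is_uniform(self, rng):
        _, phi = sample_sphere_angles([1, 0, 0, 0], 0.05, 1.0902, rng, n=self.N)
        stat = kstest(phi / (2 * np.pi), "uniform")
        assert stat.pvalue > 0.01

    def test_unpolarized_rayleigh_theta_marginal(self, rng):
        theta, _ = sample_sphere_angles([1, 0, 0, 0], 0.05, 1.0902, rng, n=self.N)
        edges = np.linspace(0.0, np.pi, 51)
        counts, _ = np.histogram(theta, bins=edges)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = (1.0 + np.cos(centers) ** 2) * np.sin(centers)
        expected = dens / dens.sum() * self.N
        assert chisquare(counts, expected).pvalue > 0.01

    def test_polarized_phi_marginal_matches_quadrature(self, rng):
        # fully x-polarized Rayleigh light scatters preferentially at
        # phi = +-90 deg; compare the sampled phi histogram with the
        # numerically integrated phase function
        from polarmc.mie import single_scatter_mueller

        stokes = np.array([1.0, 1.0, 0.0, 0.0])
        x, m = 0.05, 1.0902
        _, phi = sample_sphere_angles(stokes, x, m, rng, n=self.N)
        thetas = np.linspace(0.0, np.pi, 401)
        Ms = single_scatter_mueller(x, m, thetas)
        s11 = np.trapezoid(Ms[:, 0, 0] * np.sin(thetas), thetas)
        s12 = np.trapezoid(Ms[:, 0, 1] * np.sin(thetas), thetas)
        edges = np.linspace(0.0, 2.0 * np.pi, 41)
        centers = 0.5 * (edges[1:] + edges[:-1])
        dens = s11 + s12 * np.cos(2.0 * centers)
        expected = dens / dens.sum() * self.N
        counts, _ = np.histogram(phi, bins=edges)
        assert chisquare(counts, expected).pvalue > 0.01

    def test_cylinder_cone_constraint_and_symmetry(self, rng):
        Theta = sample_cylinder_angles([1, 0, 0, 0], X_DERMIS, M_REL, np.pi / 2, rng, n=self.N)
        assert np.all((Theta >= 0) & (Theta < 2 * np.pi))
        # unpolarized normal incidence: mirror symmetric about the
        # forward direction, so E[sin Theta] = 0
        assert abs(np.mean(np.sin(Theta))) < 5.0 / np.sqrt(self.N)

    def test_cylinder_theta_marginal_matches_quadrature(self, rng):
        stokes = np.array([1.0, 0.6, 0.0, 0.0])
        zeta = 1.1
        Theta = sample_cylinder_angles(stokes, X_DERMIS, M_REL, zeta, rng, n=self.N)
        grid = np.linspace(0.0, 2.0 * np.pi, 721)
        M = cylinder_mueller(X_DERMIS, M_REL, zeta, grid)
        dens_grid = M[:, 0, 0] + 0.6 * M[:, 0, 1]
        edges = np.linspace(0.0, 2.0 * np.pi, 41)
        counts, _ = np.histogram(Theta, bins=edges)
        expected = np.empty(40)
        for i in range(40):
            sel = (grid >= edges[i]) & (grid <= edges[i + 1])
            expected[i] = np.trapezoid(dens_grid[sel], grid[sel])
        expected *= self.N / expected.sum()
        assert chisquare(counts, expected).pvalue > 0.01
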