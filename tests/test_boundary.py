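"""Measurement-side path: patterns, ND/DN matrices, analytic disc, t^exp."""

import numpy as np
import pytest

from dbarnet.boundary import (ElectrodeLayout, PatternedData, adjacent_patterns,
                              analytic_dn_disc, best_constant_fit,
                              build_nd_matrix, disc_dn_eigenvalues,
                              scale_measurement, synthesize_voltage_data,
                              texp_scattering, trig_patterns)
from dbarnet.exceptions import ContractViolation, DomainError
from dbarnet.grids import PlaneGrid


def fd_dn_eigenvalue(sigma_inner, rho, n, m=4000):
    """Independent oracle: dense radial finite-difference solve of
    (sigma r u')' = sigma n^2 u / r on (0, 1), u(1) = 1, u(0) regular;
    returns lambda_n = sigma(1) u'(1)."""
    h = 1.0 / m
    r = (np.arange(m) + 0.5) * h  # cell centers; faces at j*h
    sigma = np.where(r < rho, sigma_inner, 1.0)
    faces = np.arange(1, m) * h
    sig_face = np.where(faces < rho, sigma_inner, 1.0)
    # tridiagonal system for u at cell centers
    main = np.zeros(m)
    lower = np.zeros(m - 1)
    upper = np.zeros(m - 1)
    rhs = np.zeros(m)
    for j in range(m):
        c_w = sig_face[j - 1] * faces[j - 1] / h if j > 0 else 0.0
        c_e = sig_face[j] * faces[j] / h if j < m - 1 else sigma[j] * 1.0 / (h / 2)
        main[j] = -(c_w + c_e) - sigma[j] * n**2 / r[j] * h
        if j > 0:
            lower[j - 1] = c_w
        if j < m - 1:
            upper[j] = c_e
        else:
            rhs[j] = -c_e * 1.0  # Dirichlet u = 1 at r = 1
    import scipy.linalg as sla
    ab = np.zeros((3, m))
    ab[0, 1:] = upper
    ab[1] = main
    ab[2, :-1] = lower
    u = sla.solve_banded((1, 1), ab, rhs)
    return (1.0 - u[-1]) / (h / 2)  # sigma(1) = 1


class TestPatterns:
    def test_trig_patterns_zero_sum_and_count(self):
        for L in (16, 32):
            pats = trig_patterns(L)
            assert pats.shape == (L - 1, L)
            assert np.allclose(pats.sum(axis=1), 0.0, atol=1e-10)
            assert np.linalg.matrix_rank(pats) == L - 1

    def test_adjacent_patterns_zero_sum(self):
        pats = adjacent_patterns(16)
        assert pats.shape == (15, 16)
        assert np.allclose(pats.sum(axis=1), 0.0)


class TestNDMatrix:
    def test_gram_identity_when_voltages_equal_currents(self):
        layout = ElectrodeLayout.disc(32, radius=1.0, width=0.15)
        pats = trig_patterns(32)
        data = PatternedData(pats, pats)
        nd = build_nd_matrix(data, layout)
        assert np.allclose(nd.matrix, np.eye(31), atol=1e-10)

    def test_homogeneous_disc_diagonal_one_over_n(self):
        layout = ElectrodeLayout.disc(32, radius=1.0)
        dn = analytic_dn_disc(1.0, 0.5, layout=layout)
        data = synthesize_voltage_data(dn, trig_patterns(32))
        nd = build_nd_matrix(data, layout)
        orders = np.r_[np.arange(1, 17), np.arange(1, 16)]
        assert np.allclose(np.diag(nd.matrix), 1.0 / orders, atol=1e-10)
        off = nd.matrix - np.diag(np.diag(nd.matrix))
        assert np.abs(off).max() < 1e-10

    def test_width_scaling_consistent_with_normalization(self):
        """Doubling all |e_l| doubles every raw pairing entry; after the
        unit-norm pattern convention the operator matrix is unchanged (the
        pattern normalization absorbs exactly the extra width factor)."""
        layout1 = ElectrodeLayout.disc(16, radius=1.0, width=0.1)
        layout2 = ElectrodeLayout.disc(16, radius=1.0, width=0.2)
        pats = trig_patterns(16)
        rng = np.random.default_rng(0)
        volts = rng.normal(size=pats.shape)
        volts -= volts.mean(axis=1, keepdims=True)
        data = PatternedData(pats, volts)
        raw1 = np.einsum("ml,l,nl->mn", pats, layout1.widths, volts)
        raw2 = np.einsum("ml,l,nl->mn", pats, layout2.widths, volts)
        assert np.allclose(raw2, 2.0 * raw1, atol=1e-12)
        m1 = build_nd_matrix(data, layout1).matrix
        m2 = build_nd_matrix(data, layout2).matrix
        assert np.allclose(m2, m1, atol=1e-12)

    def test_nd_dn_inverse_pair(self):
        dn = analytic_dn_disc(2.0, 0.5)
        data = synthesize_voltage_data(dn, trig_patterns(32))
        nd = build_nd_matrix(data, dn.layout)
        prod = nd.matrix @ nd.invert().matrix
        assert np.allclose(prod, np.eye(31), atol=1e-9)


class TestScaling:
    def test_identity_for_unit_scales(self):
        dn = analytic_dn_disc(1.5, 0.4)
        data = synthesize_voltage_data(dn, trig_patterns(32))
        nd = build_nd_matrix(data, dn.layout)
        scaled = scale_measurement(nd, r_max=1.0, sigma_0=1.0)
        assert np.allclose(scaled.matrix, nd.matrix)

    def test_physical_disc_scales_to_unit_reference(self):
        from dbarnet.boundary import _apply_disc_nd
        layout = ElectrodeLayout.disc(32, radius=0.15, width=0.025)
        pats = trig_patterns(32)
        volts = _apply_disc_nd(pats, 0.15, 0.3)
        nd = build_nd_matrix(PatternedData(pats, volts), layout)
        scaled = scale_measurement(nd, r_max=0.15, sigma_0=0.3)
        orders = np.r_[np.arange(1, 17), np.arange(1, 16)]
        assert np.allclose(np.diag(scaled.matrix), 1.0 / orders, atol=1e-9)

    def test_scale_round_trip(self):
        dn = analytic_dn_disc(2.0, 0.5)
        data = synthesize_voltage_data(dn, trig_patterns(32))
        nd = build_nd_matrix(data, dn.layout)
        scaled = scale_measurement(nd, r_max=0.2, sigma_0=0.5)
        assert np.allclose(scaled.matrix * (0.2 / 0.5), nd.matrix)

    def test_nonpositive_scale_rejected(self):
        dn = analytic_dn_disc(2.0, 0.5)
        data = synthesize_voltage_data(dn, trig_patterns(32))
        nd = build_nd_matrix(data, dn.layout)
        with pytest.raises(DomainError):
            scale_measurement(nd, r_max=-1.0, sigma_0=1.0)


class TestBestConstantFit:
    def test_recovers_homogeneous_conductivity(self):
        from dbarnet.boundary import _apply_disc_nd
        layout = ElectrodeLayout.disc(32, radius=0.15, width=0.025)
        pats = trig_patterns(32)
        data = PatternedData(pats, _apply_disc_nd(pats, 0.15, 0.3))
        assert abs(best_constant_fit(data, layout) - 0.3) < 0.003

    def test_homogeneity_in_data_scale(self):
        from dbarnet.boundary import _apply_disc_nd
        layout = ElectrodeLayout.disc(32, radius=1.0)
        pats = trig_patterns(32)
        v = _apply_disc_nd(pats, 1.0, 0.5)
        s1 = best_constant_fit(PatternedData(pats, v), layout)
        s2 = best_constant_fit(PatternedData(pats, 2.0 * v), layout)
        assert np.isclose(s2, s1 / 2.0)

    def test_stable_under_measurement_noise(self, rng):
        dn = analytic_dn_disc(1.0, 0.5)
        clean = synthesize_voltage_data(dn, trig_patterns(32))
        noisy = synthesize_voltage_data(dn, trig_patterns(32),
                                        noise_snr_db=60.0, rng=rng)
        s_clean = best_constant_fit(clean, dn.layout)
        s_noisy = best_constant_fit(noisy, dn.layout)
        assert abs(s_noisy - s_clean) / s_clean < 0.05


class TestAnalyticDisc:
    def test_unit_conductivity_gives_homogeneous_eigenvalues(self):
        orders = np.arange(1, 9)
        lam = disc_dn_eigenvalues(1.0, 0.5, orders)
        assert np.allclose(lam, orders)

    def test_vanishing_inclusion_limit(self):
        orders = np.arange(1, 9)
        lam = disc_dn_eigenvalues(2.0, 1e-9, orders)
        assert np.allclose(lam, orders, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    def test_eigenvalues_match_dense_fd_solve(self, n):
        exact = disc_dn_eigenvalues(2.0, 0.5, np.array([n]))[0]
        fd = fd_dn_eigenvalue(2.0, 0.5, n)
        assert abs(fd - exact) / exact < 0.005

    def test_invalid_rho_rejected(self):
        with pytest.raises(DomainError):
            analytic_dn_disc(2.0, 1.5)


class TestSynthesizeData:
    def test_noise_free_round_trip(self):
        dn = analytic_dn_disc(2.0, 0.5)
        data = synthesize_voltage_data(dn, trig_patterns(32))
        nd = build_nd_matrix(data, dn.layout)
        assert np.allclose(np.linalg.inv(nd.matrix), dn.matrix, atol=1e-8)

    def test_60db_noise_small_round_trip_error(self, rng):
        dn = analytic_dn_disc(2.0, 0.5)
        data = synthesize_voltage_data(dn, trig_patterns(32),
                                       noise_snr_db=60.0, rng=rng)
        nd = build_nd_matrix(data, dn.layout)
        rel = (np.linalg.norm(np.linalg.inv(dn.matrix) - nd.matrix)
               / np.linalg.norm(nd.matrix))
        assert rel < 0.01

    def test_current_conservation_preserved(self, rng):
        dn = analytic_dn_disc(2.0, 0.5)
        data = synthesize_voltage_data(dn, adjacent_patterns(32),
                                       noise_snr_db=80.0, rng=rng,
                                       family="adjacent")
        assert np.allclose(data.currents.sum(axis=1), 0.0, atol=1e-12)


class TestTexp:
    def test_homogeneous_disc_vanishes(self):
        dn = analytic_dn_disc(1.0, 0.5)
        sd = texp_scattering(dn, PlaneGrid(16, 4.0), R_meas=4.0)
        assert np.abs(sd.t).max() < 1e-4

    def test_matches_exact_series_for_concentric_disc(self):
        """t^exp has a closed form on the concentric disc:
        2 pi sum_n (-|k|^2)^n / (n!)^2 (lambda_n - n)."""
        from scipy.special import factorial
        dn = analytic_dn_disc(2.0, 0.5)
        kg = PlaneGrid(16, 4.0)
        sd = texp_scattering(dn, kg, R_meas=4.0)
        orders = np.arange(1, 60)
        lam = disc_dn_eigenvalues(2.0, 0.5, orders)
        for idx in [(8, 12), (11, 5), (3, 8)]:
            k = kg.z[idx]
            if abs(k) > 4.0 or k == 0:
                continue
            terms = ((-(abs(k) ** 2)) ** orders / factorial(orders) ** 2
                     * (lam - orders))
            exact = 2 * np.pi * terms.sum()
            assert abs(sd.t[idx] - exact) < 1e-4 * max(1.0, abs(exact))

    def test_quadrature_refinement_converges(self):
        dn = analytic_dn_disc(1.0, 0.5)
        kg = PlaneGrid(16, 4.0)
        coarse = np.abs(texp_scattering(dn, kg, 4.0, n_quad=64).t).max()
        fine = np.abs(texp_scattering(dn, kg, 4.0, n_quad=512).t).max()
        assert fine <= coarse + 1e-12

    def test_unscaled_dn_rejected(self):
        dn = analytic_dn_disc(2.0, 0.5)
        dn.scaled = False
        with pytest.raises(ContractViolation):
            texp_scattering(dn, PlaneGrid(16, 4.0))


class TestGeneralBoundary:
    def test_spline_normals_match_analytic_on_chest_curve(self):
        # chest-like smooth curve r(t) = 1 + 0.15 cos 2t - 0.05 cos 3t
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        r = 1 + 0.15 * np.cos(2 * t) - 0.05 * np.cos(3 * t)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        layout = ElectrodeLayout(16, widths=np.full(16, 0.2), radius=None,
                                 boundary_samples=pts)
        tq = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        nu = layout.normals(tq)
        # analytic outward normal of the polar curve
        rr = 1 + 0.15 * np.cos(2 * tq) - 0.05 * np.cos(3 * tq)
        dr = -0.3 * np.sin(2 * tq) + 0.15 * np.sin(3 * tq)
        z = rr * np.exp(1j * tq)
        dz = (dr + 1j * rr) * np.exp(1j * tq)
        nu_exact = -1j * dz / np.abs(dz)
        assert np.abs(nu - nu_exact).max() < 1e-3
        assert np.allclose(np.abs(nu), 1.0)

    def test_r_max_of_curve(self):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        pts = np.column_stack([1.3 * np.cos(t), 0.8 * np.sin(t)])
        layout = ElectrodeLayout(16, widths=np.full(16, 0.2), radius=None,
                                 boundary_samples=pts)
        assert abs(layout.r_max - 1.3) < 1e-3
        unit = layout.scaled_to_unit()
        assert abs(unit.r_max - 1.0) < 1e-6
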