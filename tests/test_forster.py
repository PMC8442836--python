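"""Förster engine: orientation factors, couplings, overlaps, rates, R0."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanofret import forster
from nanofret.io import ChromophoreSite, Spectrum
from nanofret.steady_state import efficiency_from_distance

EPS0 = 8.8541878128e-12
DEBYE = 3.33564e-30  # C·m
HC_J_CM = 1.98644586e-23  # J·cm


def site(pos, dip, mag=1.0, band="dye", label="", center=2.0, fwhm=0.1):
    return ChromophoreSite(np.array(pos, float), np.array(dip, float), mag, band, label, center, fwhm)


class TestOrientationFactor:
    def test_in_plane_parallel(self):
        assert forster.orientation_factor([0, 0, 1], [0, 0, 1], [1, 0, 0]) == pytest.approx(1.0)

    def test_head_to_tail(self):
        assert forster.orientation_factor([1, 0, 0], [1, 0, 0], [1, 0, 0]) == pytest.approx(-2.0)

    def test_orthogonal_null(self):
        assert forster.orientation_factor([1, 0, 0], [0, 1, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            forster.orientation_factor([0, 0, 0], [0, 0, 1], [1, 0, 0])

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            forster.orientation_factor([2, 0, 0], [0, 0, 1], [1, 0, 0])

    @given(st.integers(0, 10_000))
    def test_bounded_by_two(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(3, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        k = forster.orientation_factor(*v)
        assert -2.0 - 1e-9 <= k <= 2.0 + 1e-9

    def test_isotropic_average_two_thirds(self):
        k2 = forster.isotropic_kappa_squared(1_000_000, seed=1)
        assert k2 == pytest.approx(2.0 / 3.0, abs=0.005)


class TestCoupling:
    def test_unit_case_against_si_oracle(self):
        # κ=1, 1 D · 1 D, vacuum, 1 nm — evaluate J = κ μDμA/(4πε₀ r³)
        # in SI units and convert to cm⁻¹ independently of the 5.04 constant
        d = site([0, 0, 0], [0, 0, 1])
        a = site([10, 0, 0], [0, 0, 1])
        res = forster.point_dipole_coupling(d, a, screening_n2=1.0)
        j_si = DEBYE * DEBYE / (4 * np.pi * EPS0 * (1e-9) ** 3)  # joules
        j_cm = j_si / HC_J_CM
        # the conventional 5.04 prefactor is the SI value 5.034 rounded
        assert res.J_meV * forster.CM_PER_MEV == pytest.approx(j_cm, rel=2e-3)
        assert res.J_meV == pytest.approx(0.625, abs=0.001)

    def test_screened_example(self):
        d = site([0, 0, 0], [0, 0, 1], mag=6.0)
        a = site([35, 0, 0], [0, 0, 1], mag=4.0)
        res = forster.point_dipole_coupling(d, a, screening_n2=2.0)
        assert res.J_meV == pytest.approx(0.175, abs=0.001)

    def test_inverse_cube_law(self):
        d = site([0, 0, 0], [0, 0, 1])
        a1 = site([10, 0, 0], [0, 0, 1])
        a2 = site([20, 0, 0], [0, 0, 1])
        j1 = forster.point_dipole_coupling(d, a1, 1.0).J_meV
        j2 = forster.point_dipole_coupling(d, a2, 1.0).J_meV
        assert j1 / j2 == pytest.approx(8.0, rel=1e-9)

    def test_sign_tracks_kappa(self):
        d = site([0, 0, 0], [1, 0, 0])
        a = site([10, 0, 0], [1, 0, 0])
        res = forster.point_dipole_coupling(d, a, 1.0)
        assert res.kappa == pytest.approx(-2.0)
        assert res.J_meV < 0

    def test_contact_guard(self):
        d = site([0, 0, 0], [0, 0, 1])
        a = site([0.5, 0, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="guard"):
            forster.point_dipole_coupling(d, a, 1.0)


class TestLineshapeAndOverlap:
    def test_unit_area(self):
        ls = forster.gaussian_lineshape(2.0, 0.06)
        e = np.linspace(1.5, 2.5, 20001)
        assert np.trapezoid(ls.evaluate(e), e) == pytest.approx(1.0, abs=1e-9)

    def test_peak_value(self):
        ls = forster.gaussian_lineshape(2.0, 0.06)
        assert ls.evaluate(np.array([2.0]))[0] == pytest.approx(
            1.0 / (ls.sigma * np.sqrt(2 * np.pi))
        )

    def test_translation_invariance(self):
        a = forster.gaussian_lineshape(1.8, 0.06)
        b = forster.gaussian_lineshape(2.2, 0.06)
        e = np.linspace(1.0, 3.0, 40001)
        assert np.trapezoid(a.evaluate(e), e) == pytest.approx(np.trapezoid(b.evaluate(e), e))

    def test_identical_gaussians_closed_form(self):
        sigma = 0.05
        ls = forster.gaussian_lineshape(2.0, sigma / forster.FWHM_TO_SIGMA)
        theta = forster.spectral_overlap(ls, ls)
        assert theta == pytest.approx(1.0 / (2 * sigma * np.sqrt(np.pi)), rel=1e-6)

    def test_separated_gaussians_closed_form(self):
        sigma = 0.05
        mk = lambda c: forster.gaussian_lineshape(c, sigma / forster.FWHM_TO_SIGMA)
        theta0 = forster.spectral_overlap(mk(2.0), mk(2.0))
        theta = forster.spectral_overlap(mk(2.0), mk(2.0 + 2 * sigma))
        assert theta / theta0 == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_disjoint_supports_zero_with_warning(self):
        a = forster.gaussian_lineshape(1.5, 0.02)
        b = forster.gaussian_lineshape(2.5, 0.02)
        with pytest.warns(RuntimeWarning, match="overlap"):
            assert forster.spectral_overlap(a, b) == 0.0

    def test_spectrum_energy_conversion_matches_lineshape(self):
        # a narrow Gaussian in wavelength ≈ the equivalent energy Gaussian
        lam0, sig_lam = 620.0, 6.0
        lam = np.linspace(560, 680, 4001)
        spec = Spectrum(lam, np.exp(-0.5 * ((lam - lam0) / sig_lam) ** 2), "emission")
        e0 = forster.HC_EV_NM / lam0
        sig_e = e0 / lam0 * sig_lam
        ls = forster.gaussian_lineshape(e0, sig_e / forster.FWHM_TO_SIGMA)
        theta_ss = forster.spectral_overlap(spec, ls)
        theta_ll = forster.spectral_overlap(ls, ls)
        assert theta_ss == pytest.approx(theta_ll, rel=0.01)


class TestRates:
    def test_printed_scale(self):
        k = forster.forster_rate(0.15, 2.45)
        assert 1.0 / k == pytest.approx(1.90, abs=0.01)

    def test_zero_coupling(self):
        assert forster.forster_rate(0.0, 2.45) == 0.0

    def test_quadratic_in_J(self):
        assert forster.forster_rate(0.3, 1.0) == pytest.approx(4 * forster.forster_rate(0.15, 1.0))

    def test_single_acceptor_consistency(self):
        d = site([0, 0, 0], [0, 0, 1], mag=6.0, center=2.05, fwhm=0.10)
        a = site([30, 0, 0], [0, 0, 1], mag=4.0, band="Qy", center=1.85, fwhm=0.06)
        res = forster.total_rate(d, [a], screening_n2=2.0)
        cpl = forster.point_dipole_coupling(d, a, 2.0)
        theta = forster.spectral_overlap(
            forster.gaussian_lineshape(2.05, 0.10), forster.gaussian_lineshape(1.85, 0.06)
        )
        assert res.k_total == pytest.approx(forster.forster_rate(cpl.J_meV, theta))

    def test_duplicated_acceptor_doubles_total(self):
        d = site([0, 0, 0], [0, 0, 1], mag=6.0)
        a = site([30, 0, 0], [0, 0, 1], mag=4.0, band="Qy", center=1.95, fwhm=0.08, label="A")
        one = forster.total_rate(d, [a], 2.0)
        two = forster.total_rate(d, [a, a], 2.0)
        assert two.k_total == pytest.approx(2 * one.k_total, rel=1e-12)

    def test_far_field_r6_law(self):
        d = site([0, 0, 0], [0, 0, 1], mag=6.0, center=1.95, fwhm=0.08)
        accs = [site([40 + 5 * i, 3 * i, 0], [0, 0, 1], 4.0, "Qy", f"A{i}", 1.95, 0.08) for i in range(3)]
        base = forster.total_rate(d, accs, 2.0)
        doubled = forster.total_rate(
            d, [site(2 * a.position, a.dipole_unit, 4.0, "Qy", a.label, 1.95, 0.08) for a in accs], 2.0
        )
        assert doubled.transfer_time / base.transfer_time == pytest.approx(64.0, rel=1e-9)

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(5)
        d = site([1, 2, 3], [0, 0, 1], mag=6.0, center=1.95, fwhm=0.08)
        accs = [site([35, 5, -4], [0, 1, 0], 4.0, "Qy", "A", 1.85, 0.06)]
        base = forster.total_rate(d, accs, 2.0).k_total
        # random rotation + translation applied to every site
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([10.0, -20.0, 5.0])
        d2 = site(q @ d.position + shift, q @ d.dipole_unit, 6.0, "dye", "", 1.95, 0.08)
        a2 = [site(q @ accs[0].position + shift, q @ accs[0].dipole_unit, 4.0, "Qy", "A", 1.85, 0.06)]
        assert forster.total_rate(d2, a2, 2.0).k_total == pytest.approx(base, rel=1e-9)

    def test_empty_acceptors_rejected(self):
        with pytest.raises(ValueError):
            forster.total_rate(site([0, 0, 0], [0, 0, 1]), [], 2.0)


class TestDistanceScan:
    # coplanar sites with dipoles along the membrane normal: κ = 1 at every
    # separation, so the pure r⁻⁶ law is visible without orientation drift
    donor = site([50, 0, 23], [0, 0, 1], mag=6.0, center=2.05, fwhm=0.10)
    acceptor = site([0, 0, 23], [0, 0, 1], 4.0, "Qy", "Chl", 1.85, 0.06)

    def test_scan_consistent_with_total_rate(self):
        lateral = np.linalg.norm(self.donor.position[:2]) / 10.0
        table = forster.distance_scan(
            self.donor, np.zeros(3), [self.acceptor], [lateral], screening_n2=2.0
        )
        direct = forster.total_rate(self.donor, [self.acceptor], 2.0)
        assert table[0, 1] == pytest.approx(direct.transfer_time, rel=1e-9)

    def test_monotone_in_distance(self):
        table = forster.distance_scan(
            self.donor, np.zeros(3), [self.acceptor], np.linspace(3, 15, 20), screening_n2=2.0
        )
        assert np.all(np.diff(table[:, 1]) > 0)

    def test_far_field_log_slope_six(self):
        table = forster.distance_scan(
            self.donor, np.zeros(3), [self.acceptor], np.geomspace(20, 60, 12), screening_n2=2.0
        )
        slope = np.polyfit(np.log(table[:, 0]), np.log(table[:, 1]), 1)[0]
        assert slope == pytest.approx(6.0, abs=0.1)

    def test_guard_skips_with_warning(self):
        with pytest.warns(RuntimeWarning, match="guard"):
            table = forster.distance_scan(
                self.donor, np.zeros(3), [self.acceptor], [0.2, 5.0], screening_n2=2.0
            )
        assert table.shape[0] == 1

    def test_isotropic_mode_uses_two_thirds(self):
        tab_iso = forster.distance_scan(
            self.donor, np.zeros(3), [self.acceptor], [10.0], 2.0, orientation="isotropic_avg"
        )
        # rebuild with explicit κ² = 2/3
        res = forster.total_rate(
            forster.ChromophoreSite(
                np.array([100.0 * self.donor.position[0] / np.linalg.norm(self.donor.position[:2]),
                          100.0 * self.donor.position[1] / np.linalg.norm(self.donor.position[:2]),
                          self.donor.position[2]]),
                self.donor.dipole_unit, 6.0, "dye", "", 2.05, 0.10,
            ),
            [self.acceptor], 2.0, kappa_override=np.sqrt(2 / 3),
        )
        assert tab_iso[0, 1] == pytest.approx(res.transfer_time, rel=1e-9)


class TestForsterRadius:
    lam = np.linspace(480, 760, 2001)
    shape = np.exp(-0.5 * ((lam - 600.0) / 8.0) ** 2)
    donor_em = Spectrum(lam, shape, "emission")
    acc_abs = Spectrum(lam, shape, "absorption")

    def test_sixth_root_scaling(self):
        r1 = forster.forster_radius(self.donor_em, self.acc_abs, epsilon_max=1e5)
        r2 = forster.forster_radius(self.donor_em, self.acc_abs, epsilon_max=64e5)
        assert r2 / r1 == pytest.approx(2.0, rel=1e-9)

    def test_zero_kappa2(self):
        assert forster.forster_radius(self.donor_em, self.acc_abs, kappa2=0.0) == 0.0

    def test_unit_analysis_oracle(self):
        # literal unit-by-unit evaluation: R0^6 = 8.79e-5 κ² n⁻⁴ φ J_λ (Å⁶)
        kappa2, n, phi = 2 / 3, 1.4, 0.9
        eps_max = 1e5
        f = self.shape
        eps = eps_max * self.shape / self.shape.max()
        J = np.trapezoid(f * eps * self.lam**4, self.lam) / np.trapezoid(f, self.lam)
        expected_nm = (8.79e-5 * kappa2 * n**-4 * phi * J) ** (1 / 6) / 10.0
        got = forster.forster_radius(self.donor_em, self.acc_abs, kappa2, n, phi, eps_max)
        assert got == pytest.approx(expected_nm, rel=1e-9)

    def test_golden_rule_and_radius_routes_agree(self):
        # one donor–acceptor pair built from the same Gaussian spectra and
        # κ²: E = k/(k + 1/τ_D) must match E = 1/(1+(r/R0)^6). The two
        # routes are bridged by the standard dipole-strength relations
        # μ²(D²) = 9.186e-3·∫(ε/ν̄)dν̄ and A(s⁻¹) = 3.1366e-7·ν̄³·μ².
        lam0, sig_lam = 600.0, 8.0
        mu_D, mu_A, tau_D, kappa2 = 5.0, 4.0, 4.0, 2.0 / 3.0
        nu0 = 1e7 / lam0
        sig_nu = 1e7 / lam0**2 * sig_lam
        eps_max = nu0 * mu_A**2 / 9.186e-3 / (sig_nu * np.sqrt(2 * np.pi))
        phi_D = 3.1366e-7 * nu0**3 * mu_D**2 * tau_D * 1e-9
        R0 = forster.forster_radius(self.donor_em, self.acc_abs, kappa2, 1.0, phi_D, eps_max)
        theta = forster.spectral_overlap(self.donor_em, self.acc_abs)
        e0 = forster.HC_EV_NM / lam0
        fwhm_e = (e0 / lam0 * sig_lam) / forster.FWHM_TO_SIGMA
        for r in (0.8 * R0, R0, 1.3 * R0):
            d = site([0, 0, 0], [0, 0, 1], mu_D, "dye", "D", e0, fwhm_e)
            a = site([10 * r, 0, 0], [0, 0, 1], mu_A, "Qy", "A", e0, fwhm_e)
            cpl = forster.point_dipole_coupling(d, a, 1.0, kappa_override=np.sqrt(kappa2))
            k = forster.forster_rate(cpl.J_meV, theta)
            e_gold = k / (k + 1.0 / tau_D)
            e_r0 = efficiency_from_distance(r, R0)
            assert e_gold == pytest.approx(e_r0, rel=0.05)


class TestDefaultGeometryScale:
    def test_couplings_below_half_meV(self):
        # dyes outside the bilayer, ≥ 3 nm from the rim chromophores: far
        # weaker than the 1–10 meV couplings inside the antenna protein
        from nanofret.synth import DiscGeometry, gen_disc_geometry

        sites_list = gen_disc_geometry(DiscGeometry(n_tr=20, seed=11), leaflets=[1] * 20)
        tr = [s for s in sites_list if s.label.startswith("TR")]
        chl = [s for s in sites_list if not s.label.startswith("TR")]
        for d in tr:
            for a in chl:
                if np.linalg.norm(d.position - a.position) / 10.0 < 3.0:
                    continue
                assert abs(forster.point_dipole_coupling(d, a, 2.0).J_meV) < 0.5
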