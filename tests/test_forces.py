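"""Synthesis, vorticity, Lamb vector, pillbox integration, wall traction."""
import numpy as np
import pytest

from anisowomersley.constitutive import (
    AnisotropyRatios,
    scales_from_config,
    tensor_from_ratios,
)
from anisowomersley.forces import (
    ECGeometry,
    FlowField,
    ec_force,
    force_ratio_angle,
    lamb_radial,
    near_wall_radial_force,
    synthesize,
    vorticity,
    wall_traction,
)
from anisowomersley.solver import solve_harmonic, solve_mono


def _analytic_field(grid, uz_fn, ut_fn, Nt=8):
    t = np.arange(Nt) / Nt
    r = grid.nodes
    uz = np.tile(uz_fn(r)[:, None], (1, Nt))
    ut = np.tile(ut_fn(r)[:, None], (1, Nt))
    return FlowField(grid=grid, times=t, uz=uz, utheta=ut, alpha=1.0)


class TestSynthesis:
    def test_single_harmonic_at_t0_is_real_part(self, grid20, aniso):
        sol = solve_mono(grid20, 8.0, aniso)
        f = synthesize([sol], Nt=16)
        assert np.allclose(f.uz[:, 0], sol.Uz.real, atol=1e-15)

    def test_periodicity(self, grid20, aniso):
        sols = [solve_harmonic(grid20, 8.0, h, aniso, a) for h, a in enumerate((1.0, 0.5))]
        f = synthesize(sols, Nt=32)
        # value at t* = 1 equals value at t* = 0 by integer-harmonic synthesis
        recon = sum(
            np.real(s.Uz * np.exp(1j * 2 * np.pi * s.h * 1.0)) for s in sols
        )
        assert np.allclose(f.uz[:, 0], recon, atol=1e-13)

    def test_cycle_mean_is_steady_harmonic(self, grid20, aniso):
        sols = [
            solve_harmonic(grid20, 8.0, h, aniso, a)
            for h, a in enumerate((1.0, 0.6, 0.3))
        ]
        f = synthesize(sols, Nt=64)
        assert np.allclose(f.uz.mean(axis=1), sols[0].Uz.real, atol=1e-14)

    def test_no_slip_rows(self, grid20, aniso):
        sols = [solve_harmonic(grid20, 8.0, h, aniso, 1.0) for h in range(3)]
        f = synthesize(sols, Nt=32)
        assert np.abs(f.uz[-1]).max() < 1e-10 and np.abs(f.utheta[-1]).max() < 1e-10

    def test_mixed_grids_rejected(self, grid20, grid150, aniso):
        s1 = solve_mono(grid20, 8.0, aniso)
        s2 = solve_mono(grid150, 8.0, aniso)
        with pytest.raises(ValueError):
            synthesize([s1, s2])


class TestVorticity:
    def test_solid_body_swirl(self, grid20):
        f = _analytic_field(grid20, lambda r: 0 * r, lambda r: r)
        _, om_z = vorticity(f)
        assert np.allclose(om_z, 2.0, atol=1e-11)

    def test_poiseuille_azimuthal_vorticity(self, grid20):
        f = _analytic_field(grid20, lambda r: 1 - r**2, lambda r: 0 * r)
        om_t, _ = vorticity(f)
        assert np.allclose(om_t, 2 * grid20.nodes[:, None], atol=1e-11)

    def test_quadratic_swirl(self, grid20):
        f = _analytic_field(grid20, lambda r: 0 * r, lambda r: r**2 - r)
        _, om_z = vorticity(f)
        assert np.allclose(om_z, (3 * grid20.nodes - 2)[:, None], atol=1e-11)


class TestLambRadial:
    def test_poiseuille_centripetal_term(self, grid20):
        f = _analytic_field(grid20, lambda r: 1 - r**2, lambda r: 0 * r)
        ell = lamb_radial(f)
        r = grid20.nodes[:, None]
        assert np.allclose(ell, -2 * r * (1 - r**2), atol=1e-11)

    def test_zero_field(self, grid20):
        f = _analytic_field(grid20, lambda r: 0 * r, lambda r: 0 * r)
        assert np.abs(lamb_radial(f)).max() == 0.0

    def test_isotropic_output_is_pure_centripetal(self, grid150, iso):
        sols = [solve_harmonic(grid150, 10.0, h, iso, a) for h, a in enumerate((1.0, 0.5))]
        f = synthesize(sols, Nt=32)
        ell = lamb_radial(f)
        centripetal = f.uz * (grid150.D @ f.uz)
        assert np.abs(ell - centripetal).max() <= 1e-12

    def test_sign_structure_inward_for_decreasing_axial_flow(self, grid20):
        """With u_theta = 0 and u_z >= 0 decreasing in r, l_r <= 0 everywhere."""
        f = _analytic_field(grid20, lambda r: (1 - r**2) ** 2, lambda r: 0 * r)
        assert lamb_radial(f).max() <= 1e-12

    def test_monoharmonic_frequency_content_dc_and_double(self, grid150, aniso):
        """For a pure h=1 field, l_r holds only DC and the 2x frequency."""
        sol = solve_mono(grid150, 8.0, aniso)
        f = synthesize([sol], Nt=64)
        ell_mid = lamb_radial(f)[100, :]
        X = np.abs(np.fft.rfft(ell_mid)) / 64
        total = X.sum()
        assert (X[0] + X[2]) / total > 1 - 1e-12
        assert X[1] / total < 1e-13


class TestECForce:
    def setup_method(self):
        self.scales = scales_from_config(R=0.012)
        self.ec = ECGeometry()

    def test_zero_field_zero_force(self, grid20):
        f = _analytic_field(grid20, lambda r: 0 * r, lambda r: 0 * r)
        F = ec_force(f, self.scales, self.ec)
        assert np.abs(F.F_EC).max() == 0.0
        assert np.all(F.F_EC >= 0.0)

    def test_constant_force_density_integrates_exactly(self):
        """Constant f_r inside the pillbox gives F = A_EC * delta_EC * f0."""
        # u_z = sqrt(1 + 2r) has centripetal term u du/dr = 1 exactly, so
        # l_r = 1 throughout (smooth on [0, 1], spectrally representable).
        from anisowomersley.spectral import cgl_grid

        g = cgl_grid(60)
        f = _analytic_field(g, lambda r: np.sqrt(1 + 2 * r), lambda r: 0 * r)
        F = ec_force(f, self.scales, self.ec)
        f0 = self.scales.rho * self.scales.U0**2 / self.scales.R  # l_r = 1
        expect = self.ec.A_EC * self.ec.delta_EC * f0
        assert np.allclose(F.F_EC, expect, rtol=1e-8)

    def test_quadrature_against_adaptive_oracle(self, grid150, aniso):
        from scipy.integrate import quad

        sols = [solve_harmonic(grid150, 17.62, h, aniso, a) for h, a in enumerate((1.0, 0.76))]
        f = synthesize(sols, Nt=8)
        F = ec_force(f, self.scales, self.ec, n_quad=256)
        ell = np.ascontiguousarray(lamb_radial(f)[:, 3])
        d_star = self.ec.delta_EC / self.scales.R
        val, _ = quad(
            lambda r: abs(grid150.barycentric_eval(ell, [r])[0]),
            1 - d_star,
            1.0,
            epsabs=1e-18,
            epsrel=1e-10,
        )
        expect = self.ec.A_EC * self.scales.rho * self.scales.U0**2 * val
        assert F.F_EC[3] == pytest.approx(expect, rel=1e-6)

    def test_pillbox_thicker_than_vessel_rejected(self, grid20):
        f = _analytic_field(grid20, lambda r: 1 - r**2, lambda r: 0 * r)
        with pytest.raises(ValueError):
            ec_force(f, scales_from_config(R=0.5e-6), self.ec)

    def test_unresolvable_pillbox_rejected(self, grid20):
        f = _analytic_field(grid20, lambda r: 1 - r**2, lambda r: 0 * r)
        tiny = ECGeometry(A_EC=100e-12, V_EC=1e-24)
        with pytest.raises(ValueError):
            ec_force(f, self.scales, tiny)

    def test_nt_refinement_stability(self, grid150, aniso):
        """F_EC statistics stable to 0.1% beyond 256 phases per cycle."""
        sols = [
            solve_harmonic(grid150, 17.62, h, aniso, a)
            for h, a in enumerate((1.00, 0.76, 0.45, 0.28, 0.20, 0.12))
        ]
        means = []
        for Nt in (256, 512):
            f = synthesize(sols, Nt=Nt)
            means.append(ec_force(f, self.scales, self.ec).F_EC.mean())
        assert abs(means[1] - means[0]) / means[0] < 1e-3


class TestWallTraction:
    def test_steady_poiseuille_wall_shear(self, grid150, iso):
        sol = solve_harmonic(grid150, 5.0, 0, iso, 1.0)
        f = synthesize([sol], Nt=4)
        scales = scales_from_config(R=0.01)
        tensor = tensor_from_ratios(scales.nu_zz, iso)
        tau = wall_traction(f, tensor, scales)
        expect = -0.5 * scales.rho * scales.nu_zz * scales.U0 / scales.R
        assert np.allclose(tau, expect, rtol=1e-10)

    def test_zero_field_zero_traction(self, grid20, iso):
        f = _analytic_field(grid20, lambda r: 0 * r, lambda r: 0 * r)
        scales = scales_from_config(R=0.01)
        tensor = tensor_from_ratios(scales.nu_zz, iso)
        assert np.abs(wall_traction(f, tensor, scales)).max() == 0.0

    def test_anisotropic_coupling_term_additive(self, grid150, aniso):
        """tau_w differs from the isotropic projection by exactly
        rho nu_ztheta (d_r u_theta - u_theta/r) at the wall."""
        sols = [solve_mono(grid150, 8.0, aniso)]
        f = synthesize(sols, Nt=16)
        scales = scales_from_config(R=0.01)
        t_aniso = tensor_from_ratios(scales.nu_zz, aniso)
        t_iso = tensor_from_ratios(
            scales.nu_zz, AnisotropyRatios(0.0, aniso.gamma, aniso.delta)
        )
        diff = wall_traction(f, t_aniso, scales) - wall_traction(f, t_iso, scales)
        s_theta = (grid150.D @ f.utheta)[-1, :] - f.utheta[-1, :]
        expect = scales.rho * t_aniso.nu_ztheta * scales.U0 / scales.R * s_theta
        assert np.allclose(diff, expect, atol=1e-18, rtol=1e-9)


class TestForceRatioAngle:
    def test_zero_radial_force(self):
        chi, phi = force_ratio_angle(np.zeros(4), np.ones(4))
        assert np.all(chi == 0.0) and np.all(phi == 0.0)

    def test_equal_forces_give_quarter_pi(self):
        chi, phi = force_ratio_angle(np.ones(3), np.ones(3))
        assert np.allclose(chi, 1.0) and np.allclose(phi, np.pi / 4)

    def test_vanishing_axial_force_sentinels(self):
        chi, phi = force_ratio_angle(np.array([1.0, -1.0, 0.0]), np.zeros(3))
        assert chi[0] == np.inf and chi[1] == np.inf and chi[2] == 0.0
        assert phi[0] == pytest.approx(np.pi / 2)
        assert phi[1] == pytest.approx(-np.pi / 2)

    def test_unit_pascal_over_reference_area_is_100_pN(self):
        """tau_w = 1 Pa on A_ref = 100 um^2 -> F_z = 100 pN exactly."""
        F_z = 1.0 * 100e-12
        assert F_z * 1e12 == pytest.approx(100.0, rel=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            force_ratio_angle(np.ones(3), np.ones(4))


def test_near_wall_proxy_scales_with_reference_area(grid150, aniso):
    sol = solve_mono(grid150, 8.0, aniso)
    f = synthesize([sol], Nt=16)
    scales = scales_from_config(R=0.01)
    ec = ECGeometry()
    F1 = near_wall_radial_force(f, scales, ec, A_ref=100e-12)
    F2 = near_wall_radial_force(f, scales, ec, A_ref=200e-12)
    assert np.allclose(F2, 2 * F1, rtol=1e-14)
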