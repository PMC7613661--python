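"""Thick-walled cylinder equilibrium, residual-stress calibration and the
release verifications (axial excision, radial cut)."""

import numpy as np
import pytest

from arterynotch import (
    ArteryGeometry,
    prestretch_profile,
    simulate_axial_release,
    simulate_radial_cut,
    solve_equilibrium,
    stretch_profiles,
)
from arterynotch.units import mmhg_to_kpa


class TestPrestretchProfile:
    def test_published_endpoints(self, geom):
        resid = prestretch_profile(geom, 98.9)
        assert resid.lambda_circ(geom.r_i0) == pytest.approx(0.9715, abs=1e-4)
        assert resid.lambda_circ(geom.r_o0) == pytest.approx(1.0247, abs=1e-4)

    def test_opening_angle_factor(self, geom):
        assert prestretch_profile(geom, 98.9).k == pytest.approx(1.3788, abs=1e-4)

    def test_zero_angle_is_unstretched(self, geom):
        resid = prestretch_profile(geom, 0.0)
        np.testing.assert_allclose(resid.lambda_circ_profile, 1.0, atol=1e-14)

    def test_profile_brackets_unity_and_increases(self, geom):
        prof = prestretch_profile(geom, 98.9).lambda_circ_profile
        assert prof[0] < 1 < prof[-1]
        assert np.all(np.diff(prof) > 0)

    def test_angle_out_of_range(self, geom):
        with pytest.raises(ValueError):
            prestretch_profile(geom, 360.0)

    def test_retention_scaling(self, geom):
        full = prestretch_profile(geom, 98.9)
        half = prestretch_profile(geom, 98.9, retain_frac_circ=0.5)
        np.testing.assert_allclose(
            half.lambda_circ_profile - 1.0,
            0.5 * (full.lambda_circ_profile - 1.0),
            rtol=1e-12,
            atol=1e-15,
        )
        quarter = prestretch_profile(geom, 98.9, retain_frac_axial=0.5)
        assert quarter.lambda_axial_eff == pytest.approx(1.195)


class TestEquilibrium:
    def test_unloaded_unstressed_is_identity(self, geom, params, fibers):
        resid = prestretch_profile(geom, 0.0, lambda_axial=1.0)
        w = solve_equilibrium(geom, resid, params, fibers, 0.0)
        np.testing.assert_allclose(w.r, w.R, atol=1e-10)
        np.testing.assert_allclose(w.sigma_tt, 0.0, atol=1e-9)
        np.testing.assert_allclose(w.sigma_rr, 0.0, atol=1e-9)

    @pytest.mark.parametrize("pressure", [40.0, 100.0, 200.0])
    def test_boundary_tractions(self, geom, params, fibers, pressure):
        resid = prestretch_profile(geom, 98.9)
        w = solve_equilibrium(geom, resid, params, fibers, pressure)
        P = mmhg_to_kpa(pressure)
        assert abs(w.sigma_rr[0] + P) < 1e-3 * P
        assert abs(w.sigma_rr[-1]) < 1e-3 * P

    def test_interior_equilibrium_residual(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        w = solve_equilibrium(geom, resid, params, fibers, 100.0)
        assert w.residual_norm < 1e-3 * np.max(np.abs(w.sigma_tt))

    def test_near_incompressibility_at_high_pressure(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        w = solve_equilibrium(geom, resid, params, fibers, 200.0)
        assert np.all(np.abs(w.J_e - 1.0) < 0.02)

    def test_inner_radius_monotone_in_pressure(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        radii = [
            solve_equilibrium(geom, resid, params, fibers, p).r[0]
            for p in np.linspace(0.0, 200.0, 9)
        ]
        assert np.all(np.diff(radii) > 0)

    def test_grid_convergence(self, params, fibers):
        lam = {}
        for n in (33, 65):
            g = ArteryGeometry(n_radial=n)
            resid = prestretch_profile(g, 98.9)
            w = solve_equilibrium(g, resid, params, fibers, 100.0)
            lam[n] = w.lambda_e_theta[:: (n - 1) // 32]  # matched radii
        np.testing.assert_allclose(lam[33], lam[65], rtol=1e-3)
        rel = np.max(np.abs(lam[33] - lam[65]) / lam[65])
        assert rel < 1e-3


class TestOpeningAngleCalibration:
    def test_reproduces_published_angle(self, calibrated_phi):
        assert calibrated_phi == pytest.approx(98.9, abs=1.5)

    def test_local_minimum_bracketing(self, geom, params, fibers, calibrated_phi):
        def objective(phi):
            resid = prestretch_profile(geom, phi)
            lam = solve_equilibrium(geom, resid, params, fibers, 100.0).lambda_e_theta
            return np.sum(np.abs(lam - lam.mean()))

        f0 = objective(calibrated_phi)
        assert f0 <= objective(calibrated_phi - 5.0)
        assert f0 <= objective(calibrated_phi + 5.0)

    def test_homogenization_factor(self, geom, params, fibers, calibrated_phi):
        def cv(phi):
            resid = prestretch_profile(geom, phi)
            lam = solve_equilibrium(geom, resid, params, fibers, 100.0).lambda_e_theta
            return lam.std() / lam.mean()

        assert cv(0.0) / cv(calibrated_phi) > 3.0

    def test_stretch_nearly_uniform_at_calibrated_angle(
        self, geom, params, fibers, calibrated_phi
    ):
        resid = prestretch_profile(geom, calibrated_phi)
        lam = solve_equilibrium(geom, resid, params, fibers, 100.0).lambda_e_theta
        assert lam.std() / lam.mean() < 0.01


class TestResidualStressRelease:
    def test_axial_release_published_value(self, geom):
        resid = prestretch_profile(geom, 98.9, lambda_axial=1.39)
        assert simulate_axial_release(geom, resid, loaded_length=0.03) == pytest.approx(
            0.0216, abs=5e-4
        )

    def test_axial_release_trivial(self, geom):
        resid = prestretch_profile(geom, 0.0, lambda_axial=1.0)
        assert simulate_axial_release(geom, resid, loaded_length=1.0) == 1.0
        resid = prestretch_profile(geom, 0.0, lambda_axial=1.39)
        assert simulate_axial_release(geom, resid, loaded_length=1.39) == pytest.approx(1.0)

    def test_radial_cut_recovers_published_angle(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9, lambda_axial=1.0)
        opened = simulate_radial_cut(geom, resid, params, fibers)
        assert opened == pytest.approx(98.58, abs=1.5)
        assert opened == pytest.approx(98.9, abs=1.0)  # round trip

    def test_radial_cut_without_hoop_stress(self, geom, params, fibers):
        resid = prestretch_profile(geom, 0.0, lambda_axial=1.0)
        assert abs(simulate_radial_cut(geom, resid, params, fibers)) < 0.5

    @pytest.mark.parametrize("phi", [50.0, 130.0])
    def test_radial_cut_round_trip(self, geom, params, fibers, phi):
        resid = prestretch_profile(geom, phi, lambda_axial=1.0)
        assert simulate_radial_cut(geom, resid, params, fibers) == pytest.approx(
            phi, abs=1.0
        )

    def test_opened_angle_monotone_in_imposed_angle(self, geom, params, fibers):
        opened = [
            simulate_radial_cut(
                geom, prestretch_profile(geom, phi, lambda_axial=1.0), params, fibers
            )
            for phi in (20.0, 60.0, 100.0, 150.0)
        ]
        assert np.all(np.diff(opened) > 0)


class TestStretchProfiles:
    def test_mean_profile_is_mean_pressure_solve(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        prof = stretch_profiles(geom, resid, params, fibers, 120.0, 80.0)
        w100 = solve_equilibrium(geom, resid, params, fibers, 100.0)
        np.testing.assert_allclose(prof.mean, w100.lambda_e_theta, rtol=1e-10)

    def test_equal_pressures_give_unit_dynamic_stretch(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        prof = stretch_profiles(geom, resid, params, fibers, 100.0, 100.0)
        np.testing.assert_allclose(prof.dynamic, 1.0, atol=1e-10)

    def test_hypertension_raises_profiles_everywhere(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        normal = stretch_profiles(geom, resid, params, fibers, 120.0, 80.0)
        hyper = stretch_profiles(geom, resid, params, fibers, 160.0, 80.0)
        assert np.all(hyper.mean > normal.mean)
        assert np.all(hyper.systolic > normal.systolic)

    def test_pressure_ordering_validated(self, geom, params, fibers):
        resid = prestretch_profile(geom, 98.9)
        with pytest.raises(ValueError):
            stretch_profiles(geom, resid, params, fibers, 80.0, 120.0)
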