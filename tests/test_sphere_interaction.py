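"""Sphere-near-charged-plane interaction energies: closed forms, the
numerical Maxwell-stress backend, depletion distances, and the PEG
geometry table."""

import numpy as np
import pytest

from sdep.constants import ANGSTROM, sigma_from_area_per_charge
from sdep.double_layer import ChargedInterface, IonicMedium
from sdep.errors import DomainError, InvalidInputError, NoCrossingError
from sdep.sphere_interaction import (
    DielectricSphere,
    InteractionCurve,
    clausius_mossotti,
    dep_energy_closed,
    dep_energy_stress_tensor,
    depletion_distance,
    discussion_estimates,
    hydrostatic_energy,
    peg_geometry,
    total_energy,
)


class TestClausiusMossotti:
    def test_matched_permittivity_vanishes(self, medium01):
        assert clausius_mossotti(
            DielectricSphere(5.0, 78.5), medium01) == 0.0

    def test_low_permittivity_sphere(self, medium01, peg600):
        assert clausius_mossotti(peg600, medium01) == pytest.approx(
            -0.41018, abs=1e-5)

    def test_conductor_limit(self, medium01):
        cm = clausius_mossotti(DielectricSphere(5.0, 1e9), medium01)
        assert cm == pytest.approx(1.0, abs=1e-6)


class TestClosedFormDep:
    def test_neutral_plane_gives_zero(self, medium01, peg600):
        c = dep_energy_closed(peg600, ChargedInterface(0.0), medium01,
                              np.linspace(7, 40, 10))
        assert np.all(c.e_dep_kT == 0.0)

    def test_prefactor_value(self, medium01, dpps, peg600):
        # K_D = -2 pi a^3 CM sigma^2/(eps_w eps_0) = 37.85 kT for the
        # PEG600/PS-like parameter set
        c = dep_energy_closed(peg600, dpps, medium01, np.array([7.0]))
        assert c.K_D_J / medium01.kBT == pytest.approx(37.848, abs=0.01)

    def test_log_slope_is_minus_two_kappa(self, medium01, dpps, peg600):
        z = np.linspace(8, 50, 40)
        c = dep_energy_closed(peg600, dpps, medium01, z)
        slope = np.polyfit(z, np.log(c.e_dep_kT), 1)[0]
        assert -slope == pytest.approx(2 * medium01.kappa * ANGSTROM,
                                       rel=1e-12)

    def test_matches_brute_force_force_integration(self, medium01, dpps,
                                                   peg600):
        # oracle: E_D(z) = -int_z^inf F dz with the classical point-dipole
        # force F = 2 pi a^3 eps_w CM d(E^2)/dz on the linearized field
        from sdep.constants import EPS_0

        cm = clausius_mossotti(peg600, medium01)
        a = peg600.radius_m
        k = medium01.kappa
        e0 = dpps.sigma_C_m2 / medium01.permittivity

        def force(z_m):
            de2 = -2 * k * e0**2 * np.exp(-2 * k * z_m)
            return 2 * np.pi * a**3 * medium01.permittivity * cm * de2

        z0 = 15.0 * ANGSTROM
        zz = np.linspace(z0, z0 + 30 / k, 200001)
        e_brute = np.trapezoid(force(zz), zz)  # work from infinity to z
        c = dep_energy_closed(peg600, dpps, medium01, np.array([15.0]))
        assert c.e_dep_kT[0] == pytest.approx(
            e_brute / medium01.kBT, rel=1e-6)

    def test_sphere_touching_plane_rejected(self, medium01, dpps, peg600):
        with pytest.raises(DomainError):
            dep_energy_closed(peg600, dpps, medium01, np.array([5.0]))


class TestHydrostatic:
    def test_neutral_plane_gives_zero(self, medium01, peg600):
        c = hydrostatic_energy(peg600, ChargedInterface(0.0), medium01,
                               np.array([10.0]))
        assert np.all(c.e_hyd_kT == 0.0)

    def test_prefactor_value(self, medium01, dpps, peg600):
        c = hydrostatic_energy(peg600, dpps, medium01, np.array([7.0]))
        assert c.K_H_J / medium01.kBT == pytest.approx(37.78, abs=0.02)

    def test_point_sphere_limit_is_volume_times_pressure(self, medium01,
                                                         dpps):
        # kappa*a -> 0: E_H -> V * Pi(z) within 1%
        tiny = DielectricSphere(0.3, 10.0)
        z = np.array([12.0])
        c = hydrostatic_energy(tiny, dpps, medium01, z)
        pi0 = dpps.sigma_C_m2**2 / (2 * medium01.permittivity)
        expected = tiny.volume_m3 * pi0 * np.exp(
            -2 * medium01.kappa * z[0] * ANGSTROM)
        assert c.e_hyd_kT[0] * medium01.kBT == pytest.approx(
            expected, rel=0.01)

    def test_quadrature_log_slope(self, medium01, dpps, peg600):
        z = np.linspace(8, 45, 30)
        c = hydrostatic_energy(peg600, dpps, medium01, z)
        slope = -np.polyfit(z, np.log(c.e_hyd_kT), 1)[0]
        assert slope == pytest.approx(2 * medium01.kappa * ANGSTROM,
                                      rel=0.01)

    def test_vant_hoff_pressure_model_runs_and_exceeds_linearized(
            self, medium01, dpps, peg600):
        z = np.array([10.0, 20.0])
        lin = hydrostatic_energy(peg600, dpps, medium01, z)
        vh = hydrostatic_energy(peg600, dpps, medium01, z,
                                pressure_model="vant_hoff_grahame")
        assert np.all(vh.e_hyd_kT > 0)
        assert np.all(np.isfinite(vh.e_hyd_kT))


class TestDepletionDistance:
    def test_pure_exponential_root(self, medium01):
        k2 = 0.2  # 1/A
        z = np.linspace(5, 60, 500)
        z0 = 23.0
        amp = np.exp(k2 * z0)  # crosses 1 at exactly z0
        curve = InteractionCurve(z_A=z, e_dep_kT=amp * np.exp(-k2 * z),
                                 e_hyd_kT=np.zeros_like(z),
                                 sphere_radius_A=7.0)
        d, dstar = depletion_distance(curve, 1.0)
        assert d == pytest.approx(z0, abs=0.01)
        assert dstar == pytest.approx(z0 - 7.0, abs=0.01)

    def test_threshold_doubling_shifts_by_ln2_over_2kappa(self, medium01,
                                                          dpps, peg600):
        z = np.linspace(7, 70, 800)
        curve = total_energy(peg600, dpps, medium01, z)
        d1, _ = depletion_distance(curve, 1.0)
        d2, _ = depletion_distance(curve, 2.0)
        expected = np.log(2) / (2 * medium01.kappa * ANGSTROM)
        assert d1 - d2 == pytest.approx(expected, abs=0.03)

    def test_headline_analytical_distance(self, medium01, peg600):
        # PEG600 near a fully charged PS-like plane in 0.1 M: the summed
        # closed-form energies cross 1 kBT near 21 A
        iface = ChargedInterface(0.35)
        z = np.linspace(7, 70, 800)
        curve = total_energy(peg600, iface, medium01, z)
        d, dstar = depletion_distance(curve, 1.0)
        assert d == pytest.approx(20.81, abs=0.05)
        assert dstar == pytest.approx(d - 7.0, abs=1e-9)

    def test_no_crossing_raises(self, medium01, dpps, peg600):
        z = np.linspace(7, 30, 50)
        curve = total_energy(peg600, dpps, medium01, z)
        with pytest.raises(NoCrossingError):
            depletion_distance(curve, 1e6)

    def test_monotone_in_molecular_weight(self, medium01, dpps):
        # larger coils are repelled farther (table trend)
        prev = 0.0
        for mw in (600, 1000, 1540, 2000, 3400, 6000):
            rh, _ = peg_geometry(mw)
            sphere = DielectricSphere(rh, 10.0, mw)
            z = np.linspace(rh, rh + 90, 900)
            d, _ = depletion_distance(
                total_energy(sphere, dpps, medium01, z), 1.0)
            assert d > prev
            prev = d


class TestSymmetryAndScaling:
    def test_sign_of_charge_symmetry(self, medium01, peg600):
        z = np.linspace(8, 40, 20)
        plus = total_energy(peg600, ChargedInterface(0.35), medium01, z)
        minus = total_energy(peg600, ChargedInterface(-0.35), medium01, z)
        assert np.array_equal(plus.e_total_kT, minus.e_total_kT)

    def test_cubic_radius_scaling(self, medium01, dpps):
        # closed-form E_D and point-limit E_H scale as a^3 at fixed z
        z = np.array([30.0])
        e1 = dep_energy_closed(DielectricSphere(2.0, 10.0), dpps, medium01,
                               z).e_dep_kT[0]
        e2 = dep_energy_closed(DielectricSphere(4.0, 10.0), dpps, medium01,
                               z).e_dep_kT[0]
        assert e2 / e1 == pytest.approx(8.0, rel=1e-12)
        h1 = hydrostatic_energy(DielectricSphere(0.2, 10.0), dpps, medium01,
                                z).e_hyd_kT[0]
        h2 = hydrostatic_energy(DielectricSphere(0.4, 10.0), dpps, medium01,
                                z).e_hyd_kT[0]
        assert h2 / h1 == pytest.approx(8.0, rel=1e-3)


class TestPegGeometry:
    @pytest.mark.parametrize("mw, rh, n", [
        (600, 7.0, 13), (1000, 9.0, 22), (1540, 11.0, 35),
        (2000, 13.0, 45), (3400, 17.0, 77), (6000, 22.0, 136),
    ])
    def test_table(self, mw, rh, n):
        assert peg_geometry(mw) == (rh, n)

    def test_interpolation_between_rows(self):
        rh, _ = peg_geometry(800)
        assert 7.0 < rh < 9.0

    def test_invalid_weight(self):
        with pytest.raises(InvalidInputError):
            peg_geometry(-5.0)
        with pytest.raises(InvalidInputError):
            peg_geometry(10.0)


class TestDiscussionEstimates:
    def test_thermal_force(self, medium01, dpps):
        est = discussion_estimates(DielectricSphere(7.0, 10.0), dpps,
                                   medium01)
        assert est["thermal_force_pN"] == pytest.approx(2.94, abs=0.01)

    def test_thermal_force_halves_with_doubled_radius(self, medium01, dpps):
        f1 = discussion_estimates(DielectricSphere(7.0), dpps,
                                  medium01)["thermal_force_pN"]
        f2 = discussion_estimates(DielectricSphere(14.0), dpps,
                                  medium01)["thermal_force_pN"]
        assert f1 / f2 == pytest.approx(2.0, rel=1e-9)

    def test_hydrostatic_force_scale(self, medium01, dpps):
        # force density x sphere volume lands on the few-pN scale
        est = discussion_estimates(DielectricSphere(7.0), dpps, medium01)
        assert 1.0 < est["hydrostatic_force_pN"] < 30.0


class TestStressTensorBackend:
    def test_neutral_plane_gives_zero(self, medium01, peg600):
        c = dep_energy_stress_tensor(peg600, ChargedInterface(0.0),
                                     medium01, np.array([12.0, 20.0]))
        assert np.all(c.e_dep_kT == 0.0)

    def test_force_consistent_with_energy_derivative(self, medium01, dpps,
                                                     peg600):
        # -dE_D/dz from the integrated energy returns the force profile
        # the backend was built from (the tail integral is exponential)
        z = np.array([14.0, 18.0, 22.0, 26.0])
        c = dep_energy_stress_tensor(peg600, dpps, medium01, z,
                                     refine=False)
        e = c.e_dep_kT
        slope = -np.polyfit(z, np.log(e), 1)[0]
        force_from_e = 2 * medium01.kappa * ANGSTROM * e  # ~2k E for exp
        assert slope == pytest.approx(2 * medium01.kappa * ANGSTROM,
                                      rel=0.05)
        assert np.all(force_from_e > 0)

    def test_too_close_to_wall_rejected(self, medium01, dpps, peg600):
        with pytest.raises(DomainError):
            dep_energy_stress_tensor(peg600, dpps, medium01,
                                     np.array([7.05]), refine=False)


class TestChargeConversions:
    def test_area_per_charge_to_sigma(self):
        assert sigma_from_area_per_charge(46.0) == pytest.approx(
            0.3483, abs=5e-4)
        assert sigma_from_area_per_charge(69.8) == pytest.approx(
            0.2295, abs=5e-4)

    def test_invalid_area(self):
        with pytest.raises(InvalidInputError):
            sigma_from_area_per_charge(0.0)
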