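"""Composition-space profiles, the reflectivity kernel against an
independent transfer-matrix oracle, Fresnel normalization, smearing, and
the exclusion-distance metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdep.constants import material_nsld_1e6
from sdep.errors import (
    ExclusionBelowResolutionError,
    InvalidInputError,
    ModelInfeasibleError,
)
from sdep.reflectometry import (
    CompositionSpaceModel,
    MolecularComponent,
    PEGExclusionProfile,
    ReflectivityCurve,
    _parratt_numpy,
    exclusion_distance,
    fresnel_normalize,
    fresnel_reflectivity,
    reflectivity,
    smear_resolution,
    wavevector_q,
)


def transfer_matrix_reflectivity(Q, thickness_A, sld_1e6):
    """Independent oracle: Abeles 2x2 characteristic-matrix formalism for
    a sharp-interface slab stack (no roughness)."""
    Q = np.asarray(Q, dtype=float)
    slds = np.asarray(sld_1e6, dtype=float)
    thick = np.asarray(thickness_A, dtype=float)
    out = np.empty(len(Q))
    for iq, q in enumerate(Q):
        kz = np.sqrt((q / 2.0) ** 2
                     - 4e-6 * np.pi * (slds - slds[0]) + 0j)
        M = np.eye(2, dtype=complex)
        for j in range(1, len(slds) - 1):
            b = kz[j] * thick[j]
            cj, sj = np.cos(b), np.sin(b)
            Mj = np.array([[cj, 1j * sj / kz[j]],
                           [1j * sj * kz[j], cj]])
            M = M @ Mj
        k0, kn = kz[0], kz[-1]
        num = k0 * M[0, 0] + k0 * kn * M[0, 1] - M[1, 0] - kn * M[1, 1]
        den = k0 * M[0, 0] + k0 * kn * M[0, 1] + M[1, 0] + kn * M[1, 1]
        out[iq] = abs(num / den) ** 2
    return out


class TestWavevector:
    def test_value(self):
        assert wavevector_q(5.0, 1.0) == pytest.approx(0.043863, abs=1e-6)

    def test_limits_and_scaling(self):
        assert wavevector_q(5.0, 1e-9) == pytest.approx(0.0, abs=1e-9)
        assert wavevector_q(10.0, 1.0) == pytest.approx(
            wavevector_q(5.0, 1.0) / 2.0, rel=1e-12)

    def test_invalid_angles(self):
        with pytest.raises(InvalidInputError):
            wavevector_q(5.0, 95.0)
        with pytest.raises(InvalidInputError):
            wavevector_q(-1.0, 1.0)


class TestPegProfile:
    def test_zero_interaction_is_flat(self):
        p = PEGExclusionProfile(0.09, 9.6, 50.0, 0.0)
        z = np.linspace(0, 200, 50)
        assert np.allclose(p.volume_fraction(z), 0.09)

    def test_far_field_recovers_bulk(self):
        p = PEGExclusionProfile(0.09, 9.6, 50.0, 5.0)
        assert p.volume_fraction(500.0) == pytest.approx(0.09, rel=1e-10)

    def test_value_at_plane_of_charge(self):
        p = PEGExclusionProfile(0.5, 9.6, 10.0, 1.0)
        assert p.volume_fraction(10.0) == pytest.approx(
            0.5 * np.exp(-1.0), rel=1e-12)

    def test_monotone_in_z(self):
        p = PEGExclusionProfile(0.09, 9.6, 20.0, 8.0)
        z = np.linspace(0, 120, 300)
        assert np.all(np.diff(p.volume_fraction(z)) >= 0)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidInputError):
            PEGExclusionProfile(1.5, 9.6, 0.0, 1.0)
        with pytest.raises(InvalidInputError):
            PEGExclusionProfile(0.1, -1.0, 0.0, 1.0)
        with pytest.raises(InvalidInputError):
            PEGExclusionProfile(0.1, 9.6, 0.0, -1.0)


class TestNsldProfile:
    def test_pure_heavy_water_half_space(self):
        # b = 19.145 fm and 1.105 g/cm^3 give ~6.4e-6 A^-2
        assert material_nsld_1e6("D2O") == pytest.approx(6.36, abs=0.01)

    def test_linear_mixing_of_peg_and_solvent(self):
        # a 50:50 PEG/D2O voxel averages the two nSLDs
        peg = PEGExclusionProfile(0.5, 9.6, -1e3, 0.0)
        model = CompositionSpaceModel(
            components=[], solvent_sld_1e6=material_nsld_1e6("D2O"),
            fronting_sld_1e6=2.07, peg=peg)
        got = model.nsld_profile(np.array([50.0]))[0]
        assert got == pytest.approx(
            0.5 * 0.7 + 0.5 * material_nsld_1e6("D2O"), rel=1e-9)

    def test_zero_coverage_component_contributes_nothing(self):
        comp = MolecularComponent("ghost", 100.0, 300.0, 20.0, 10.0,
                                  coverage=0.0)
        model = CompositionSpaceModel(
            components=[comp], solvent_sld_1e6=6.36, fronting_sld_1e6=2.07)
        z = np.linspace(0, 50, 20)
        assert np.allclose(model.nsld_profile(z), 6.36)

    def test_occupancy_conservation(self):
        from sdep.synthetic import make_paper_like_truth, truth_models

        model = truth_models(make_paper_like_truth("DOPC:DOPS"))[0]
        z = np.linspace(-10, 150, 500)
        occ = model.occupancy_profiles(z)
        total = sum(occ.values())
        assert np.allclose(total, 1.0, atol=1e-9)
        assert np.all(occ["solvent"] >= -1e-9)

    def test_profile_export_round_trip(self, tmp_path):
        from sdep.synthetic import make_paper_like_truth, truth_models

        model = truth_models(make_paper_like_truth("DOPC:DOPS"))[0]
        z = np.linspace(-10, 150, 161)
        path = tmp_path / "profile.tsv"
        model.export_profile_tsv(path, z)
        data = np.loadtxt(path)
        assert data.shape[0] == len(z)
        # occupancy columns sum to one; last column is the nSLD
        assert np.allclose(data[:, 1:-1].sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(data[:, -1], model.nsld_profile(z))

    def test_overfull_model_rejected(self):
        a = MolecularComponent("a", 10.0, 100.0, 20.0, 20.0, coverage=0.8)
        b = MolecularComponent("b", 10.0, 100.0, 20.0, 20.0, coverage=0.8)
        model = CompositionSpaceModel(
            components=[a, b], solvent_sld_1e6=6.36, fronting_sld_1e6=2.07)
        with pytest.raises(ModelInfeasibleError):
            model.nsld_profile(np.array([20.0]))


class TestReflectivityKernel:
    def test_single_interface_equals_fresnel_closed_form(self):
        q = np.linspace(0.005, 0.3, 200)
        r = fresnel_reflectivity(q, 2.07, 6.36)
        kz0 = (q / 2.0).astype(complex)
        kz1 = np.sqrt(kz0**2 - 4e-6 * np.pi * (6.36 - 2.07))
        expected = np.abs((kz0 - kz1) / (kz0 + kz1)) ** 2
        assert np.allclose(r, expected, rtol=1e-12)

    def test_total_reflection_band(self):
        # below the critical edge of a denser backing, R = 1
        q = np.linspace(0.002, 0.012, 40)
        r = fresnel_reflectivity(q, 2.07, 6.36)
        qc = np.sqrt(16e-6 * np.pi * (6.36 - 2.07))
        band = q < qc
        assert band.sum() > 5
        assert np.allclose(r[band], 1.0, atol=1e-6)

    def test_zero_contrast_reflects_nothing(self):
        q = np.linspace(0.01, 0.3, 50)
        r = reflectivity(q, [0, 20, 0], [4.0, 4.0, 4.0])
        assert np.allclose(r, 0.0, atol=1e-15)

    def test_matches_transfer_matrix_oracle_on_random_stacks(self, rng):
        q = np.linspace(0.008, 0.379, 120)
        for _ in range(20):
            n = 5
            slds = rng.uniform(-0.5, 7.0, n + 2)
            thick = np.concatenate(([0.0], rng.uniform(5.0, 60.0, n), [0.0]))
            r = reflectivity(q, thick, slds)
            oracle = transfer_matrix_reflectivity(q, thick, slds)
            assert np.allclose(r, oracle, rtol=1e-10, atol=1e-14)

    def test_compiled_and_numpy_paths_agree(self):
        q = np.linspace(0.008, 0.3, 100)
        slds = np.array([2.07, 3.4, -0.3, 1.8, 6.36])
        thick = np.array([0.0, 14.0, 30.0, 9.0, 0.0])
        rough = np.array([0.0, 2.5, 3.0, 3.0, 2.0])
        assert np.allclose(reflectivity(q, thick, slds, rough),
                           _parratt_numpy(q, thick, slds, rough),
                           rtol=1e-12)

    def test_reciprocity_on_symmetric_profile(self):
        # a symmetric stack viewed from either side reflects identically
        q = np.linspace(0.02, 0.35, 80)
        slds = [1.0, 4.0, 2.0, 4.0, 1.0]
        thick = [0.0, 20.0, 15.0, 20.0, 0.0]
        fwd = reflectivity(q, thick, slds)
        rev = reflectivity(q, thick[::-1], slds[::-1])
        assert np.allclose(fwd, rev, rtol=1e-10)

    def test_non_ascending_q_rejected(self):
        with pytest.raises(InvalidInputError):
            reflectivity(np.array([0.1, 0.05]), [0, 0], [2.07, 6.36])


class TestFresnelNormalize:
    def _curve(self, q, r):
        return ReflectivityCurve(Q=q, R=r, dR=0.01 * np.maximum(r, 1e-12),
                                 dQ=0.025 * q)

    def test_structureless_interface_normalizes_to_unity(self):
        q = np.linspace(0.01, 0.3, 100)
        c = self._curve(q, fresnel_reflectivity(q, 2.07, 6.36))
        norm = fresnel_normalize(c, 2.07, 6.36)
        assert np.allclose(norm.R, 1.0, rtol=1e-12)

    def test_bilayer_oscillates_about_unity(self):
        from sdep.synthetic import make_paper_like_truth, truth_models

        model = truth_models(make_paper_like_truth("DOPC:DOPS"))[0]
        q = np.linspace(0.02, 0.3, 200)
        thick, slds, rough = model.slab_model(-10, 145, 0.5)
        c = self._curve(q, reflectivity(q, thick, slds, rough))
        norm = fresnel_normalize(c, model.fronting_sld_1e6,
                                 model.backing_sld_1e6())
        assert norm.R.max() > 1.0 > norm.R.min()

    def test_round_trip(self):
        q = np.linspace(0.02, 0.3, 60)
        c = self._curve(q, fresnel_reflectivity(q, 2.07, 6.36) * 0.7)
        rf = fresnel_reflectivity(q, 2.07, 6.36)
        norm = fresnel_normalize(c, 2.07, 6.36)
        assert np.allclose(norm.R * rf, c.R, rtol=1e-12)


class TestSmearing:
    def test_vanishing_resolution_is_identity(self):
        q = np.linspace(0.01, 0.3, 150)
        r = fresnel_reflectivity(q, 2.07, 6.36)
        c = ReflectivityCurve(Q=q, R=r, dR=0.01 * r, dQ=np.zeros_like(q))
        sm = smear_resolution(c, 1e-9 * q)
        assert np.allclose(sm.R, r, rtol=1e-6)

    def test_flat_curve_preserved(self):
        q = np.linspace(0.01, 0.3, 100)
        c = ReflectivityCurve(Q=q, R=np.full_like(q, 0.5),
                              dR=np.full_like(q, 0.01), dQ=0.025 * q)
        sm = smear_resolution(c)
        assert np.allclose(sm.R, 0.5, rtol=1e-12)

    def test_fringe_amplitude_reduced(self):
        from sdep.synthetic import make_paper_like_truth, truth_models

        model = truth_models(make_paper_like_truth("DOPC:DOPS"))[0]
        q = np.exp(np.linspace(np.log(0.02), np.log(0.3), 400))
        thick, slds, rough = model.slab_model(-10, 145, 0.5)
        r = reflectivity(q, thick, slds, rough)
        c = ReflectivityCurve(Q=q, R=r, dR=0.01 * r, dQ=0.05 * q)
        sm = smear_resolution(c)
        hi = q > 0.1
        wiggle = np.std(np.diff(np.log(r[hi])))
        wiggle_sm = np.std(np.diff(np.log(sm.R[hi])))
        assert wiggle_sm < wiggle


class TestExclusionDistance:
    def test_boundary_case_returns_plane_of_charge(self):
        p = PEGExclusionProfile(0.09, 9.6, 12.0, float(np.log(2.0)))
        assert exclusion_distance(p, 0.0) == pytest.approx(12.0, abs=1e-9)

    def test_closed_form_value(self):
        p = PEGExclusionProfile(0.09, 9.6, 0.0, 2.0)
        assert exclusion_distance(p, 0.0) == pytest.approx(5.086, abs=0.001)

    def test_numerical_root_agrees_with_closed_form(self):
        p = PEGExclusionProfile(0.09, 9.17, 40.0, 7.5)
        a = exclusion_distance(p, 10.0)
        b = exclusion_distance(p, 10.0, numerical=True)
        assert a == pytest.approx(b, abs=0.01)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.71, 19.0), st.floats(3.0, 30.0), st.floats(0.0, 80.0))
    def test_closed_form_equals_root_everywhere(self, e0, kinv, z0):
        p = PEGExclusionProfile(0.1, kinv, z0, e0)
        assert exclusion_distance(p, 0.0) == pytest.approx(
            exclusion_distance(p, 0.0, numerical=True), abs=0.01)

    def test_monotone_in_interaction_strength(self):
        dists = [exclusion_distance(
            PEGExclusionProfile(0.09, 9.6, 0.0, e0), 0.0)
            for e0 in (1.0, 2.0, 5.0, 10.0)]
        assert np.all(np.diff(dists) > 0)

    def test_weak_interaction_flagged(self):
        with pytest.raises(ExclusionBelowResolutionError):
            exclusion_distance(PEGExclusionProfile(0.09, 9.6, 0.0, 0.3))


class TestReflectivityCurveIO:
    def test_text_round_trip(self, tmp_path):
        q = np.linspace(0.01, 0.3, 30)
        c = ReflectivityCurve(Q=q, R=np.exp(-q * 10), dR=0.01 * np.ones(30),
                              dQ=0.025 * q, provenance="model")
        path = tmp_path / "curve.txt"
        c.to_text(path)
        back = ReflectivityCurve.from_text(path)
        assert np.allclose(back.Q, c.Q)
        assert np.allclose(back.R, c.R)

    def test_invariants_enforced(self):
        q = np.linspace(0.01, 0.3, 10)
        with pytest.raises(InvalidInputError):
            ReflectivityCurve(Q=q[::-1], R=np.ones(10), dR=np.ones(10),
                              dQ=q)
        with pytest.raises(InvalidInputError):
            ReflectivityCurve(Q=q, R=np.full(10, 2.0),
                              dR=np.full(10, 0.001), dQ=q)
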