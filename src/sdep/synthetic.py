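"""Synthetic data with known ground truth for the full pipeline.

Two generators stand in for the beamline and the simulation box:

* reflectivity count data for a silicon/oxide/bilayer/PEG-solution
  interface in two solvent contrasts, on the instrument's logarithmic
  Q grid (0.008–0.379 Å⁻¹, bin width 2.5% of the bin center), smeared
  with the matching resolution and Poisson-sampled around the expected
  counts;
* noisy mass-fraction profile pairs (charged/neutral membrane) whose
  free-energy difference decays as exp(-2κz) with an amplitude chosen so
  the 1 k_BT crossing sits at the tabulated depletion distance for each
  PEG molecular weight.

Every output is a deterministic function of the stored seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import erf

from .constants import (
    LIPID_PRESETS,
    MATERIALS,
    PEG_NSLD_1E6_INV_A2,
    material_nsld_1e6,
)
from .double_layer import ChargedInterface, IonicMedium
from .errors import InvalidInputError
from .md_profiles import DensityProfile
from .nr_fitting import CountCurve, ModelBuilder
from .reflectometry import (
    CompositionSpaceModel,
    MolecularComponent,
    PEGExclusionProfile,
    reflectivity,
    smearing_matrix,
)
from .sphere_interaction import DielectricSphere, peg_geometry, total_energy

__all__ = [
    "GroundTruth",
    "make_paper_like_truth",
    "truth_models",
    "make_ssblm_builder",
    "simulate_reflectivity",
    "simulate_profiles",
    "MD_DEPLETION_TABLE_A",
    "instrument_q_grid",
]

#: depletion distances d (Å, free-energy difference = 1 k_BT) embedded in
#: the synthetic profile fixtures, by PEG molecular weight
MD_DEPLETION_TABLE_A = {600: 16.0, 1000: 18.0, 1540: 20.0,
                        2000: 22.0, 3400: 26.0, 6000: 28.0}

#: densities used to convert PEG weight percent to volume fraction (g/cm³)
PEG_DENSITY = 1.13
WATER_DENSITY = 1.105  # D2O-based buffer

AREA_PER_LIPID_A2 = 72.0

_CONTRAST_CODES = {"D2O": 1, "H2O": 2, "D2O_H2O_mix": 3}


@dataclass
class GroundTruth:
    """Complete parameterization of a synthetic two-contrast experiment.

    Structural lengths in Å; ``z0_offset_A`` positions the plane of
    charge relative to the hydrophobic interface (outer tails/headgroup
    boundary).  ``incident_scale`` is the low-Q incident count level per
    bin; ``background_fraction`` the incoherent background relative to
    the incident beam.  The seed fully determines all sampled outputs.
    """

    lipid: str
    ionic_strength_M: float
    wt_pct_peg: float
    seed: int
    oxide_thickness_A: float = 15.0
    gap_A: float = 4.0
    head_thickness_A: float = 9.0
    tail_thickness_A: float = 28.0
    coverage: float = 0.95
    substrate_roughness_A: float = 2.5
    bilayer_roughness_A: float = 3.0
    peg_E0_kT: float = 0.0
    z0_offset_A: float = 4.5
    temperature_K: float = 298.15
    incident_scale: float = 1.0e6
    background_fraction: float = 5.0e-7
    q_min: float = 0.008
    q_max: float = 0.379
    bin_fraction: float = 0.025

    @property
    def medium(self) -> IonicMedium:
        return IonicMedium(self.ionic_strength_M,
                           temperature_K=self.temperature_K)

    @property
    def peg_bulk_fraction(self) -> float:
        w = self.wt_pct_peg / 100.0
        return (w / PEG_DENSITY) / (w / PEG_DENSITY
                                    + (1 - w) / WATER_DENSITY)

    @property
    def hydrophobic_interface_A(self) -> float:
        return (self.oxide_thickness_A + self.gap_A
                + self.head_thickness_A + self.tail_thickness_A)

    def exclusion_distance_A(self) -> float:
        """Ground-truth exclusion distance from the hydrophobic
        interface (requires E_0 > ln 2)."""
        kinv = self.medium.kappa_inv_A
        return self.z0_offset_A + float(
            np.log(self.peg_E0_kT / np.log(2.0))) * kinv / 2.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_paper_like_truth(lipid: str, wt_pct_peg: float = 9.1,
                          ionic_strength_M: float = 0.11,
                          seed: int = 0,
                          exclusion_target_A: Optional[float] = None
                          ) -> GroundTruth:
    """Ground truth for a supported-bilayer experiment with the polymer
    interaction strength taken from the sphere-interaction theory.

    ``lipid`` is one of DOPC, DOPC:DOPS, DOPC:DOTAP (the neutral,
    negatively and positively charged presets).  For charged presets E_0
    is the theoretical E_D + E_H prefactor of a PEG600 sphere (the
    exponential energy extrapolated to the plane of charge); the neutral
    preset keeps only a small steric residue.  If ``exclusion_target_A``
    is given, the plane-of-charge offset is placed so the true exclusion
    distance equals the target (the offset absorbs the polymer-size
    smearing that the sharp profile model does not resolve).
    """
    if lipid not in ("DOPC", "DOPC:DOPS", "DOPC:DOTAP"):
        raise InvalidInputError(f"unsupported lipid preset {lipid!r}")
    medium = IonicMedium(ionic_strength_M)
    sigma = LIPID_PRESETS[lipid]
    if sigma == 0.0:
        # neutral bilayer: only a small steric residue survives in E_0
        e0 = 1.5
    else:
        # charge-induced part: the theoretical prefactor K_D + K_H of a
        # PEG600 sphere, i.e. the exponential energy extrapolated to the
        # plane of charge (the steric part lives in the neutral baseline)
        rh, _ = peg_geometry(600)
        sphere = DielectricSphere(rh, 10.0, 600)
        curve = total_energy(sphere, ChargedInterface(sigma), medium,
                             np.array([rh]))
        e0 = float(curve.e_total_kT[0]
                   * np.exp(2 * medium.kappa * rh * 1e-10))
    truth = GroundTruth(lipid=lipid, ionic_strength_M=ionic_strength_M,
                        wt_pct_peg=wt_pct_peg, seed=seed, peg_E0_kT=e0)
    if exclusion_target_A is not None:
        kinv = medium.kappa_inv_A
        offset = exclusion_target_A - np.log(e0 / np.log(2.0)) * kinv / 2.0
        truth = replace(truth, z0_offset_A=float(offset))
    return truth


def _solvent_sld(contrast: str) -> float:
    d2o = material_nsld_1e6("D2O")
    h2o = material_nsld_1e6("H2O")
    if contrast == "D2O":
        return d2o
    if contrast == "H2O":
        return h2o
    if contrast == "D2O_H2O_mix":
        return 0.9 * d2o + 0.1 * h2o
    raise InvalidInputError(f"unknown contrast {contrast!r}")


def _build_model(oxide_t, gap, head_t, tail_t, coverage, sub_rough,
                 bil_rough, solvent_sld, peg, peg_present=True):
    """Assemble the supported-bilayer composition-space model.

    Boxes share edges (and edge roughness) so the hard components can
    never overfill space; the peak occupancy of each box follows from
    the molecular volume and the area per lipid, which keeps the total
    bilayer volume invariant under thickness changes.
    """
    comps = []
    # the silicon half-space enters as a wide box sharing its upper edge
    # (and roughness) with the oxide, so the substrate interface is
    # realized in profile space
    comps.append(MolecularComponent(
        "silicon", MATERIALS["silicon"]["b_fm"],
        MATERIALS["silicon"]["volume_A3"], center_A=-40.0, width_A=80.0,
        coverage=1.0, roughness_A=sub_rough))
    comps.append(MolecularComponent(
        "oxide", MATERIALS["silica"]["b_fm"], MATERIALS["silica"]["volume_A3"],
        center_A=oxide_t / 2.0, width_A=oxide_t, coverage=1.0,
        roughness_A=sub_rough))
    z_in = oxide_t + gap
    v_head = MATERIALS["pc_headgroup"]["volume_A3"]
    v_tail = MATERIALS["oleoyl_tails"]["volume_A3"]
    b_head = MATERIALS["pc_headgroup"]["b_fm"]
    b_tail = MATERIALS["oleoyl_tails"]["b_fm"]
    cov_head = min(coverage * v_head / (AREA_PER_LIPID_A2 * head_t), 1.0)
    cov_tail = min(coverage * 2 * v_tail / (AREA_PER_LIPID_A2 * tail_t), 1.0)
    comps.append(MolecularComponent(
        "inner_heads", b_head, v_head, center_A=z_in + head_t / 2.0,
        width_A=head_t, coverage=cov_head, roughness_A=bil_rough))
    z_tail = z_in + head_t
    comps.append(MolecularComponent(
        "tails", b_tail, v_tail, center_A=z_tail + tail_t / 2.0,
        width_A=tail_t, coverage=cov_tail, roughness_A=bil_rough))
    z_hpb = z_tail + tail_t
    comps.append(MolecularComponent(
        "outer_heads", b_head, v_head, center_A=z_hpb + head_t / 2.0,
        width_A=head_t, coverage=cov_head, roughness_A=bil_rough))
    return CompositionSpaceModel(
        components=comps, solvent_sld_1e6=solvent_sld,
        fronting_sld_1e6=material_nsld_1e6("silicon"),
        peg=peg if peg_present else None,
        substrate_roughness_A=sub_rough,
        hydrophobic_interface_A=z_hpb)


def truth_models(truth: GroundTruth,
                 contrasts=("D2O", "D2O_H2O_mix")) -> list[CompositionSpaceModel]:
    """Composition-space models of the ground truth, one per contrast.

    The PEG-bearing solution is measured in D2O (and H2O) contrast; the
    D2O/H2O mixture is the polymer-free control whose bulk nSLD matches
    the PEG solution, so its model carries no polymer profile.
    """
    kinv = truth.medium.kappa_inv_A
    z_hpb = truth.hydrophobic_interface_A
    peg = PEGExclusionProfile(
        bulk_fraction=truth.peg_bulk_fraction, debye_length_A=kinv,
        charge_plane_A=z_hpb + truth.z0_offset_A,
        interaction_strength_kT=truth.peg_E0_kT)
    models = []
    for contrast in contrasts:
        models.append(_build_model(
            truth.oxide_thickness_A, truth.gap_A, truth.head_thickness_A,
            truth.tail_thickness_A, truth.coverage,
            truth.substrate_roughness_A, truth.bilayer_roughness_A,
            _solvent_sld(contrast), peg,
            peg_present=(contrast != "D2O_H2O_mix")))
    return models


def make_ssblm_builder(truth: GroundTruth,
                       contrasts=("D2O", "D2O_H2O_mix")) -> ModelBuilder:
    """Standard fit parameterization for a two-contrast supported-bilayer
    data set.

    Free parameters: oxide thickness, substrate–bilayer gap, total tail
    thickness, lipid coverage, polymer interaction strength E_0, plane of
    charge offset from the hydrophobic interface, and one solvent nSLD
    per contrast.  The Debye length is fixed by the known ionic strength;
    headgroup thickness and roughnesses are fixed at preparation values.
    """
    kinv = truth.medium.kappa_inv_A
    c_inf = truth.peg_bulk_fraction
    head_t = truth.head_thickness_A
    sub_rough = truth.substrate_roughness_A
    bil_rough = truth.bilayer_roughness_A
    nominal = [_solvent_sld(c) for c in contrasts]

    def build(theta):
        (oxide_t, gap, tail_t, coverage, e0, z0_off, *solvents) = theta
        z_hpb = oxide_t + gap + head_t + tail_t
        peg = PEGExclusionProfile(
            bulk_fraction=c_inf, debye_length_A=kinv,
            charge_plane_A=z_hpb + z0_off, interaction_strength_kT=e0)
        return [
            _build_model(oxide_t, gap, head_t, tail_t, coverage, sub_rough,
                         bil_rough, sld, peg,
                         peg_present=(contrast != "D2O_H2O_mix"))
            for contrast, sld in zip(contrasts, solvents)
        ]

    names = ["oxide_thickness_A", "gap_A", "tail_thickness_A", "coverage",
             "E0_kT", "z0_offset_A"] \
        + [f"solvent_sld_{c}" for c in contrasts]
    bounds = [(8.0, 25.0), (0.0, 12.0), (20.0, 40.0), (0.75, 1.0),
              (0.0, 20.0), (0.0, 30.0)] \
        + [(s - 0.5, s + 0.5) for s in nominal]
    return ModelBuilder(build, names, bounds)


def instrument_q_grid(q_min: float = 0.008, q_max: float = 0.379,
                      bin_fraction: float = 0.025):
    """Logarithmic Q grid with constant fractional bin width (the bin
    width equals ``bin_fraction`` of the bin center); returns (Q, dQ
    FWHM)."""
    n = int(np.floor(np.log(q_max / q_min) / np.log1p(bin_fraction))) + 1
    q = q_min * (1.0 + bin_fraction) ** np.arange(n)
    return q, bin_fraction * q


def simulate_reflectivity(truth: GroundTruth, contrast: str = "D2O",
                          noise: bool = True,
                          oversample: int = 4) -> CountCurve:
    """Synthetic count data for one contrast condition.

    The forward reflectivity of the ground-truth model is computed on an
    oversampled grid, resolution-smeared onto the instrument Q grid, and
    converted to expected counts with an incident intensity that rises
    with Q (emulating the longer counting at high angles that keeps
    relative uncertainties roughly constant); specular and off-specular
    (background) counts are Poisson-sampled with a seed derived from the
    stored ground-truth seed and the contrast.  ``noise=False`` returns
    the expected (float) counts so that reduction recovers the model
    exactly.
    """
    model = truth_models(truth, (contrast,))[0]
    q, dq = instrument_q_grid(truth.q_min, truth.q_max, truth.bin_fraction)
    qf = np.exp(np.linspace(np.log(q[0] * 0.97), np.log(q[-1] * 1.03),
                            oversample * len(q)))
    thick, slds, rough = model.slab_model(-10.0, 160.0, dz_A=0.5)
    r_fine = reflectivity(qf, thick, slds, rough)
    r_sm = smearing_matrix(q, dq, qf) @ r_fine

    q_knee = 0.05
    incident = truth.incident_scale * (1.0 + (q / q_knee) ** 4)
    bg_expect = truth.background_fraction * incident
    spec_expect = r_sm * incident + bg_expect

    if noise:
        rng = np.random.default_rng(
            [truth.seed, _CONTRAST_CODES[contrast]])
        spec = rng.poisson(spec_expect).astype(float)
        bg_lo = rng.poisson(bg_expect).astype(float)
        bg_hi = rng.poisson(bg_expect).astype(float)
    else:
        spec, bg_lo, bg_hi = spec_expect, bg_expect, bg_expect
    return CountCurve(Q=q, specular=spec, background_low=bg_lo,
                      background_high=bg_hi, incident=incident, dQ=dq)


def simulate_profiles(mw: int, lipid: str = "DPPS",
                      noise_sigma: float = 0.015, seed: int = 0,
                      ionic_strength_M: float = 0.1,
                      z_max_A: float = 100.0, dz_A: float = 1.0
                      ) -> tuple[DensityProfile, DensityProfile]:
    """Charged/neutral mass-fraction profile pair with a known embedded
    free-energy difference.

    The neutral profile is a steric baseline (smoothed step at the
    polymer radius); the charged profile multiplies it by
    exp[-A exp(-2κz)] with A set so the 1 k_BT distance of the
    difference equals the tabulated depletion distance for this MW.
    Bin noise is Gaussian with σ = noise_sigma · sqrt(m) (counting-like,
    in units of the bulk mass fraction); mass fractions are floored at
    zero and the per-bin σ is stored with each profile.
    """
    if mw not in MD_DEPLETION_TABLE_A:
        raise InvalidInputError(
            f"MW {mw} not in the supported set {sorted(MD_DEPLETION_TABLE_A)}")
    if lipid not in ("DPPS", "DPTAP"):
        raise InvalidInputError("charged lipid preset must be DPPS or DPTAP")
    medium = IonicMedium(ionic_strength_M)
    k_invA = medium.kappa * 1e-10  # per Å
    rh, _ = peg_geometry(mw)
    d = MD_DEPLETION_TABLE_A[mw]
    amplitude = np.exp(2 * k_invA * d)

    z = np.arange(dz_A / 2.0, z_max_A, dz_A)
    baseline = 0.5 * (1.0 + erf((z - rh) / (np.sqrt(2.0) * 2.0)))
    delta_e = amplitude * np.exp(-2 * k_invA * z)
    charged_clean = baseline * np.exp(-delta_e)

    rng = np.random.default_rng([seed, mw])
    out = []
    for clean in (charged_clean, baseline):
        sig = noise_sigma * np.sqrt(np.maximum(clean, 1e-6))
        vals = np.maximum(clean + rng.normal(0.0, sig), 0.0)
        out.append(DensityProfile(z_A=z.copy(), values=vals, sigma=sig,
                                  kind="mass_fraction"))
    return out[0], out[1]
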