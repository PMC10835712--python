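"""Composition-space forward model for specular neutron reflectometry.

A supported-bilayer interface is described by molecular components
(substrate oxide, lipid headgroups, acyl chains) placed along z as
error-function-edged boxes, plus a polymer (PEG) exclusion profile whose
local volume fraction is Boltzmann-suppressed by the theoretical
exp(-2κ(z - z_0)) interaction energy:

    c(z) = c_inf * exp[-E_0 exp(-2κ(z - z_0))].

Any space not occupied by a component or polymer is filled with solvent;
the neutron scattering length density (nSLD) profile follows from the
components' coherent scattering lengths and molecular volumes, with the
PEG nSLD held constant at 0.7e-6 Å⁻².  Specular reflectivity is computed
from the micro-slabbed nSLD profile by the Parratt recursion with
Névot–Croce roughness factors, optionally normalized to the Fresnel
reflectivity of the bare substrate/solution interface and smeared with
the instrumental Q resolution.

Lengths are Å, Q in Å⁻¹, and all SLDs at this interface are expressed in
units of 1e-6 Å⁻² unless stated otherwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf

from .constants import PEG_NSLD_1E6_INV_A2
from .errors import (
    ExclusionBelowResolutionError,
    InvalidInputError,
    ModelInfeasibleError,
)

__all__ = [
    "MolecularComponent",
    "PEGExclusionProfile",
    "CompositionSpaceModel",
    "ReflectivityCurve",
    "wavevector_q",
    "peg_volume_fraction",
    "nsld_profile",
    "reflectivity",
    "fresnel_reflectivity",
    "fresnel_normalize",
    "smear_resolution",
    "smearing_matrix",
    "exclusion_distance",
]

LN2 = float(np.log(2.0))


def wavevector_q(wavelength_A: float, theta_deg) -> float | np.ndarray:
    """Specular scattering wavevector Q = 4π sin(θ)/λ (Å⁻¹)."""
    th = np.asarray(theta_deg, dtype=float)
    if wavelength_A <= 0:
        raise InvalidInputError("wavelength must be positive")
    if np.any(th < 0) or np.any(th >= 90):
        raise InvalidInputError("theta must lie in [0, 90) degrees")
    out = 4 * np.pi * np.sin(np.radians(th)) / wavelength_A
    return out if out.shape else float(out)


@dataclass(frozen=True)
class MolecularComponent:
    """A molecular group occupying an erf-edged box along z.

    ``scattering_length_fm`` is the summed coherent scattering length per
    formula unit; ``volume_A3`` its molecular volume; the box spans
    ``center_A ± width_A/2`` with edge roughness ``roughness_A`` and peak
    volume occupancy ``coverage``.
    """

    name: str
    scattering_length_fm: float
    volume_A3: float
    center_A: float
    width_A: float
    coverage: float = 1.0
    roughness_A: float = 2.5

    def __post_init__(self) -> None:
        if not self.volume_A3 > 0:
            raise InvalidInputError(f"{self.name}: molecular volume must be > 0")
        if not 0.0 <= self.coverage <= 1.0:
            raise InvalidInputError(f"{self.name}: coverage must be in [0, 1]")
        if self.width_A < 0:
            raise InvalidInputError(f"{self.name}: width must be >= 0")

    @property
    def nsld_1e6(self) -> float:
        """b/V in units of 1e-6 Å⁻²."""
        return self.scattering_length_fm * 1e-5 / self.volume_A3 * 1e6

    def occupancy(self, z_A) -> np.ndarray:
        z = np.asarray(z_A, dtype=float)
        lo = self.center_A - self.width_A / 2.0
        hi = self.center_A + self.width_A / 2.0
        s = max(self.roughness_A, 1e-6) * np.sqrt(2.0)
        return self.coverage * 0.5 * (erf((z - lo) / s) - erf((z - hi) / s))


@dataclass(frozen=True)
class PEGExclusionProfile:
    """Polymer volume-fraction profile near a charged plane.

    c(z) = c_inf exp[-E(z)] with E(z) = E_0 exp(-2κ(z - z_0)): ``E_0`` is
    the interaction free energy (k_BT) of the polymer at the plane of
    charge ``z_0``; κ⁻¹ is the Debye length; far from the surface the
    profile recovers the bulk volume fraction ``c_inf``.
    """

    bulk_fraction: float
    debye_length_A: float
    charge_plane_A: float
    interaction_strength_kT: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bulk_fraction <= 1.0:
            raise InvalidInputError("bulk volume fraction must be in [0, 1]")
        if not self.debye_length_A > 0:
            raise InvalidInputError("Debye length must be positive")
        if self.interaction_strength_kT < 0:
            raise InvalidInputError("interaction strength must be >= 0")

    def energy_kT(self, z_A) -> np.ndarray:
        z = np.asarray(z_A, dtype=float)
        arg = -2.0 * (z - self.charge_plane_A) / self.debye_length_A
        return self.interaction_strength_kT * np.exp(np.minimum(arg, 50.0))

    def volume_fraction(self, z_A) -> np.ndarray:
        return self.bulk_fraction * np.exp(-self.energy_kT(z_A))


def peg_volume_fraction(profile: PEGExclusionProfile, z_A) -> np.ndarray:
    """Unscaled polymer volume fraction c(z) on a grid (bulk value far
    away, Boltzmann-suppressed toward the plane of charge)."""
    return profile.volume_fraction(z_A)


@dataclass
class CompositionSpaceModel:
    """Ordered molecular components plus an optional PEG profile and the
    solvent that fills the remaining space.

    ``solvent_sld_1e6`` and ``fronting_sld_1e6`` (the substrate the beam
    travels through, silicon here) are in 1e-6 Å⁻².  The hydrophobic
    interface — the boundary between the outer-leaflet acyl chains and
    headgroups, the origin for exclusion distances — is recorded in
    ``hydrophobic_interface_A``.
    """

    components: list[MolecularComponent]
    solvent_sld_1e6: float
    fronting_sld_1e6: float
    peg: Optional[PEGExclusionProfile] = None
    peg_sld_1e6: float = PEG_NSLD_1E6_INV_A2
    substrate_roughness_A: float = 2.5
    hydrophobic_interface_A: float = 0.0

    def hard_occupancy(self, z_A) -> np.ndarray:
        z = np.asarray(z_A, dtype=float)
        total = np.zeros_like(z)
        for comp in self.components:
            total += comp.occupancy(z)
        if np.any(total > 1.0 + 1e-9):
            raise ModelInfeasibleError(
                f"component volume occupancy exceeds 1 "
                f"(max {total.max():.6f})")
        return total

    def occupancy_profiles(self, z_A) -> dict[str, np.ndarray]:
        """Volume occupancy of every component, the (space-scaled) PEG,
        and the solvent; sums to 1 at every z."""
        z = np.asarray(z_A, dtype=float)
        out: dict[str, np.ndarray] = {}
        total = np.zeros_like(z)
        for comp in self.components:
            occ = comp.occupancy(z)
            out[comp.name] = occ
            total = total + occ
        if np.any(total > 1.0 + 1e-9):
            raise ModelInfeasibleError("component volume occupancy exceeds 1")
        if self.peg is not None:
            # polymer fills a fraction of the *available* space
            peg_occ = self.peg.volume_fraction(z) * (1.0 - total)
            out["peg"] = peg_occ
            total = total + peg_occ
        out["solvent"] = 1.0 - total
        return out

    def nsld_profile(self, z_A) -> np.ndarray:
        """Average nSLD(z) in 1e-6 Å⁻²: Σ φ_i b_i/V_i + φ_peg ρ_peg +
        φ_solvent ρ_solvent."""
        z = np.asarray(z_A, dtype=float)
        occ = self.occupancy_profiles(z)
        rho = np.zeros_like(z)
        for comp in self.components:
            rho += occ[comp.name] * comp.nsld_1e6
        if self.peg is not None:
            rho += occ["peg"] * self.peg_sld_1e6
        rho += occ["solvent"] * self.solvent_sld_1e6
        return rho

    def backing_sld_1e6(self) -> float:
        """Asymptotic nSLD of the bulk solution (solvent plus dissolved
        polymer at its bulk volume fraction)."""
        if self.peg is None:
            return self.solvent_sld_1e6
        c = self.peg.bulk_fraction
        return c * self.peg_sld_1e6 + (1.0 - c) * self.solvent_sld_1e6

    def export_profile_tsv(self, path, z_A) -> None:
        """Write the occupancy decomposition and nSLD profile as TSV
        (z_A, one column per component plus peg/solvent, nsld_1e6)."""
        z = np.asarray(z_A, dtype=float)
        occ = self.occupancy_profiles(z)
        rho = self.nsld_profile(z)
        names = list(occ)
        header = "z_A\t" + "\t".join(names) + "\tnsld_1e6"
        data = np.column_stack([z] + [occ[n] for n in names] + [rho])
        np.savetxt(path, data, delimiter="\t", header=header)

    def slab_model(self, z_min_A: float, z_max_A: float,
                   dz_A: float = 0.5):
        """Micro-slab (thickness, SLD) discretization of the continuous
        profile for the reflectivity kernel.

        The fronting half-space is the substrate and the backing the bulk
        solution; all interfacial roughness is realized in the profile
        itself (erf edges), so the slab stack carries no additional
        Névot–Croce factors.  ``z_min_A`` should sit a few roughness
        widths inside the substrate and ``z_max_A`` in the bulk.
        """
        z = np.arange(z_min_A + dz_A / 2.0, z_max_A, dz_A)
        rho = self.nsld_profile(z)
        slds = np.concatenate(([self.fronting_sld_1e6], rho,
                               [self.backing_sld_1e6()]))
        thick = np.concatenate(([0.0], np.full(len(z), dz_A), [0.0]))
        rough = np.zeros(len(slds))
        return thick, slds, rough


def nsld_profile(model: CompositionSpaceModel, z_A) -> np.ndarray:
    """Functional wrapper around :meth:`CompositionSpaceModel.nsld_profile`."""
    return model.nsld_profile(z_A)


@dataclass
class ReflectivityCurve:
    """A reduced specular reflectivity curve: Q (Å⁻¹, ascending), R,
    1-σ uncertainty dR, and resolution width dQ (FWHM), with provenance
    (``model``, ``measured-synthetic``, ...)."""

    Q: np.ndarray
    R: np.ndarray
    dR: np.ndarray
    dQ: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.dR = np.asarray(self.dR, dtype=float)
        self.dQ = np.asarray(self.dQ, dtype=float)
        if not (len(self.Q) == len(self.R) == len(self.dR) == len(self.dQ)):
            raise InvalidInputError("Q, R, dR, dQ must have equal length")
        if np.any(self.Q <= 0) or np.any(np.diff(self.Q) <= 0):
            raise InvalidInputError("Q must be positive and strictly ascending")
        if np.any(self.R < -3 * self.dR - 1e-12):
            raise InvalidInputError("R more negative than its uncertainty allows")
        if np.any(self.R > 1.0 + 3 * self.dR + 1e-9):
            raise InvalidInputError("R exceeds 1 beyond its uncertainty")

    def to_text(self, path) -> None:
        header = ("reduced specular reflectivity\n"
                  f"provenance: {self.provenance}\n"
                  "columns: Q(1/A) R dR dQ(FWHM)")
        np.savetxt(path, np.column_stack([self.Q, self.R, self.dR, self.dQ]),
                   header=header)

    @classmethod
    def from_text(cls, path, provenance: str = "file") -> "ReflectivityCurve":
        data = np.loadtxt(path, comments="#")
        if data.ndim != 2 or data.shape[1] < 4:
            raise InvalidInputError(
                "expected 4-column (Q, R, dR, dQ) whitespace text")
        return cls(Q=data[:, 0], R=data[:, 1], dR=data[:, 2], dQ=data[:, 3],
                   provenance=provenance)


def _parratt_numpy(Q: np.ndarray, thick: np.ndarray, slds: np.ndarray,
                   rough: np.ndarray) -> np.ndarray:
    kz = np.sqrt((Q[None, :] / 2.0).astype(complex) ** 2
                 - 4e-6 * np.pi * (slds[:, None] - slds[0]))
    n = len(slds)
    r = np.zeros(len(Q), dtype=complex)
    for i in range(n - 2, -1, -1):
        k1, k2 = kz[i], kz[i + 1]
        rij = (k1 - k2) / (k1 + k2) * np.exp(-2.0 * k1 * k2
                                             * rough[i + 1] ** 2)
        if i == n - 2:
            r = rij
        else:
            beta = np.exp(2j * k2 * thick[i + 1])
            r = (rij + r * beta) / (1.0 + rij * r * beta)
    return np.abs(r) ** 2


try:  # optional compiled kernel; the numpy recursion is the reference
    from numba import njit

    @njit(cache=False)
    def _parratt_kernel(Q, thick, slds, rough):  # pragma: no cover
        nq = Q.shape[0]
        n = slds.shape[0]
        c = np.empty(n)
        for i in range(n):
            c[i] = 4e-6 * np.pi * (slds[i] - slds[0])
        out = np.empty(nq)
        for iq in range(nq):
            q2 = Q[iq] * Q[iq] / 4.0
            r = 0.0 + 0.0j
            arg = q2 - c[n - 1]
            if arg >= 0.0:
                k2 = complex(np.sqrt(arg), 0.0)
            else:
                k2 = complex(0.0, np.sqrt(-arg))
            for i in range(n - 2, -1, -1):
                arg = q2 - c[i]
                if arg >= 0.0:
                    k1 = complex(np.sqrt(arg), 0.0)
                else:
                    k1 = complex(0.0, np.sqrt(-arg))
                rij = (k1 - k2) / (k1 + k2)
                s = rough[i + 1]
                if s > 0.0:
                    rij = rij * np.exp(-2.0 * k1 * k2 * s * s)
                if i == n - 2:
                    r = rij
                else:
                    beta = np.exp(2j * k2 * thick[i + 1])
                    r = (rij + r * beta) / (1.0 + rij * r * beta)
                k2 = k1
            out[iq] = abs(r) ** 2
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def reflectivity(Q, thickness_A: Sequence[float], sld_1e6: Sequence[float],
                 roughness_A: Optional[Sequence[float]] = None) -> np.ndarray:
    """Specular reflectivity |r|² of a slab stack by the Parratt recursion.

    ``sld_1e6[0]`` is the fronting half-space (the medium the beam arrives
    through) and ``sld_1e6[-1]`` the backing; ``roughness_A[i]`` is the
    Névot–Croce width of the interface *above* layer i (i.e. between
    layers i-1 and i).  Below the critical edge of a denser backing the
    result is 1 to within 1e-6.  A compiled kernel is used when numba is
    importable; it agrees with the pure-numpy recursion to rounding.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 1 or np.any(np.diff(Q) <= 0):
        raise InvalidInputError("Q must be a strictly ascending 1-D array")
    slds = np.asarray(sld_1e6, dtype=float)
    thick = np.asarray(thickness_A, dtype=float)
    n = len(slds)
    if roughness_A is None:
        rough = np.zeros(n)
    else:
        rough = np.asarray(roughness_A, dtype=float)
    if _HAVE_NUMBA:
        return _parratt_kernel(Q, thick, slds, rough)
    return _parratt_numpy(Q, thick, slds, rough)


def fresnel_reflectivity(Q, fronting_sld_1e6: float,
                         backing_sld_1e6: float) -> np.ndarray:
    """Reflectivity of the ideal single interface between two half-spaces."""
    return reflectivity(Q, [0.0, 0.0],
                        [fronting_sld_1e6, backing_sld_1e6])


def fresnel_normalize(curve: ReflectivityCurve, substrate_sld_1e6: float,
                      solvent_sld_1e6: float) -> ReflectivityCurve:
    """Divide a curve by the Fresnel reflectivity of the bare
    substrate/solution interface (uncertainty scales multiplicatively;
    points where R_F = 0 are flagged with NaN rather than divided)."""
    rf = fresnel_reflectivity(curve.Q, substrate_sld_1e6, solvent_sld_1e6)
    bad = rf == 0.0
    safe = np.where(bad, 1.0, rf)
    out = ReflectivityCurve.__new__(ReflectivityCurve)
    out.Q = curve.Q.copy()
    out.R = np.where(bad, np.nan, curve.R / safe)
    out.dR = np.where(bad, np.nan, curve.dR / safe)
    out.dQ = curve.dQ.copy()
    out.provenance = curve.provenance + " (Fresnel-normalized)"
    return out


def smearing_matrix(Q_out: np.ndarray, dQ_fwhm: np.ndarray,
                    Q_in: Optional[np.ndarray] = None) -> np.ndarray:
    """Row-stochastic Gaussian resolution matrix mapping a model sampled
    on ``Q_in`` to the measured grid ``Q_out`` (σ = dQ/2.355; rows
    renormalized, which handles the endpoints one-sidedly)."""
    if Q_in is None:
        Q_in = Q_out
    sig = np.maximum(np.asarray(dQ_fwhm, dtype=float), 1e-12) / 2.355
    W = np.exp(-0.5 * ((Q_out[:, None] - Q_in[None, :]) / sig[:, None]) ** 2)
    return W / W.sum(axis=1, keepdims=True)


def smear_resolution(curve: ReflectivityCurve,
                     dQ_fwhm=None) -> ReflectivityCurve:
    """Convolve a curve with the Gaussian instrumental resolution on its
    own grid.  ``dQ_fwhm`` defaults to the curve's dQ column; dQ -> 0
    reduces to the identity."""
    dq = curve.dQ if dQ_fwhm is None else np.broadcast_to(
        np.asarray(dQ_fwhm, dtype=float), curve.Q.shape)
    if np.any(dq < 0):
        raise InvalidInputError("dQ must be non-negative")
    W = smearing_matrix(curve.Q, dq)
    out = ReflectivityCurve.__new__(ReflectivityCurve)
    out.Q = curve.Q.copy()
    out.R = W @ curve.R
    out.dR = np.sqrt(W**2 @ curve.dR**2)
    out.dQ = np.asarray(dq, dtype=float).copy()
    out.provenance = curve.provenance + " (smeared)"
    return out


def exclusion_distance(peg: PEGExclusionProfile,
                       hydrophobic_interface_A: float = 0.0,
                       numerical: bool = False) -> float:
    """Distance from the hydrophobic interface at which the polymer
    density drops to half its solution (bulk) density.

    Closed form: z_half = z_0 + ln(E_0/ln 2) / (2κ); requires E_0 > ln 2
    (otherwise the half-density point lies below the plane of charge and
    the exclusion region is below resolution).  With ``numerical`` the
    crossing is found by bisection on the profile and cross-checked
    against the closed form to 0.01 Å.
    """
    e0 = peg.interaction_strength_kT
    if e0 < LN2:
        raise ExclusionBelowResolutionError(
            f"E_0 = {e0:.3g} k_BT <= ln 2: no half-density crossing above "
            "the plane of charge")
    z_half = peg.charge_plane_A \
        + np.log(e0 / LN2) * peg.debye_length_A / 2.0
    if numerical:
        from scipy.optimize import brentq
        half = 0.5 * peg.bulk_fraction

        def f(z):
            return peg.volume_fraction(z) - half

        lo = peg.charge_plane_A
        hi = z_half + 10.0 * peg.debye_length_A
        z_num = brentq(f, lo, hi, xtol=1e-4)
        if abs(z_num - z_half) > 0.01:
            raise InvalidInputError(
                "numerical half-density root disagrees with the closed form")
        z_half = z_num
    return float(z_half - hydrophobic_interface_A)
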