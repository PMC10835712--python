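"""Physical constants, unit conversions, and small material tables.

Internal calculations are SI; public interfaces use the units customary in
membrane biophysics: Å (or nm) for lengths, mol/L for ionic strength, C/m²
for surface charge density, k_BT for energies, and 10⁻⁶ Å⁻² for neutron
scattering length densities (nSLD).
"""

from __future__ import annotations

from scipy.constants import (
    Avogadro as N_A,
    Boltzmann as K_B,
    R as R_GAS,
    elementary_charge as E_CHARGE,
    epsilon_0 as EPS_0,
)

__all__ = [
    "N_A", "K_B", "R_GAS", "E_CHARGE", "EPS_0",
    "ANGSTROM", "NM", "DEFAULT_TEMPERATURE_K", "DEFAULT_REL_PERMITTIVITY",
    "WATER_VISCOSITY_PA_S", "PEG_NSLD_1E6_INV_A2", "PEG_MONOMER_MASS_DA",
    "WATER_MASS_DA", "PEG_RH_TABLE_A", "LIPID_PRESETS", "MATERIALS",
    "sigma_from_area_per_charge", "kBT",
]

ANGSTROM = 1e-10  # m
NM = 1e-9  # m

DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_REL_PERMITTIVITY = 78.5  # water at ambient conditions
WATER_VISCOSITY_PA_S = 8.9e-4

#: nSLD of poly(ethylene glycol), held constant (units of 1e-6 Å^-2).
PEG_NSLD_1E6_INV_A2 = 0.7

#: Ethylene-oxide repeat-unit mass and the mass of the terminating water
#: (H + OH end groups), Da.  A PEG chain of n monomers has mass 44.05 n + 18.02.
PEG_MONOMER_MASS_DA = 44.05
WATER_MASS_DA = 18.02

#: Hydrodynamic radius of PEG coils by molecular weight (Å).
PEG_RH_TABLE_A = {600: 7.0, 1000: 9.0, 1540: 11.0, 2000: 13.0,
                  3400: 17.0, 6000: 22.0}


def sigma_from_area_per_charge(area_A2: float, valence: int = 1) -> float:
    """Surface charge density (C/m², magnitude) from the area per unit
    charge in Å² (e.g. one elementary charge per 46 Å² -> 0.35 C/m²)."""
    if area_A2 <= 0:
        from .errors import InvalidInputError
        raise InvalidInputError(f"area per charge must be positive, got {area_A2}")
    return valence * E_CHARGE / (area_A2 * ANGSTROM**2)


def kBT(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in J."""
    return K_B * temperature_K


# Lipid presets: signed surface charge density of fully charged monolayers
# (DPPS carries one negative charge per 46 Å², DPTAP one positive per
# 69.8 Å²) and of the 1:1 mixtures used on supported bilayers.
def _preset(area_A2: float | None, sign: int) -> float:
    return 0.0 if area_A2 is None else sign * sigma_from_area_per_charge(area_A2)


LIPID_PRESETS: dict[str, float] = {
    "DPPS": _preset(46.0, -1),        # -0.348 C/m², prints as 0.35
    "DPTAP": _preset(69.8, +1),       # +0.230 C/m²
    "DPPC": 0.0,
    "DOPC": 0.0,
    "DOPC:DOPS": _preset(92.0, -1),   # 1:1 mixture, half the DPPS density
    "DOPC:DOTAP": _preset(139.6, +1),
}


# Coherent scattering lengths (fm, summed per formula unit) and molecular
# volumes (Å³) for the components of a supported-bilayer reflectometry model.
# Editable literature defaults; D2O follows from b = 2 b_D + b_O = 19.145 fm
# and density 1.105 g/cm³.
MATERIALS: dict[str, dict[str, float]] = {
    "silicon": {"b_fm": 4.1491, "volume_A3": 20.02},
    "silica": {"b_fm": 15.7551, "volume_A3": 45.35},
    "D2O": {"b_fm": 19.145, "volume_A3": 30.10},
    "H2O": {"b_fm": -1.675, "volume_A3": 30.00},
    "pc_headgroup": {"b_fm": 60.1, "volume_A3": 331.0},
    "oleoyl_tails": {"b_fm": -29.2, "volume_A3": 984.0},
}


def material_nsld_1e6(name: str) -> float:
    """nSLD of a packaged material in units of 1e-6 Å^-2 (b/V)."""
    m = MATERIALS[name]
    return m["b_fm"] * 1e-5 / m["volume_A3"] * 1e6
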