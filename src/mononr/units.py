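"""Centralized unit conversions.

Internal conventions: lengths in Å, scattering lengths in Å (inputs in fm),
surface tension / pressure in mN·m⁻¹, pressure-tensor components in bar,
diffusion coefficients in 10⁻⁷ cm²·s⁻¹ (numerically equal to Å²·ns⁻¹).
"""

from __future__ import annotations

FM_TO_ANGSTROM = 1.0e-5
"""1 fm = 1e-5 Å; converts tabulated scattering lengths to Å."""

BAR_ANGSTROM_TO_MN_PER_M = 1.0e-2
"""1 bar·Å = 1e5 Pa · 1e-10 m = 1e-5 N·m⁻¹ = 1e-2 mN·m⁻¹."""

ATM_TO_BAR = 1.01325

AVOGADRO = 6.02214076e23

#: force-unit → pN conversion factors accepted in wall-force inputs
FORCE_TO_PN = {
    "pN": 1.0,
    "nN": 1.0e3,
    # NAMD reports forces in kcal/(mol·Å): 1 kcal/mol/Å = 69.4786 pN
    "kcal/mol/A": 69.47694845598684,
}

PN_PER_ANGSTROM_TO_MN_PER_M = 10.0
"""1 pN·Å⁻¹ = 1e-12 N / 1e-10 m = 1e-2 N·m⁻¹ = 10 mN·m⁻¹."""

PRESSURE_TO_BAR = {"bar": 1.0, "atm": ATM_TO_BAR}


def pressure_to_bar(value, unit: str):
    try:
        return value * PRESSURE_TO_BAR[unit]
    except KeyError:
        raise ValueError(f"undeclared pressure unit {unit!r}; expected one of {sorted(PRESSURE_TO_BAR)}")


def force_to_pn(value, unit: str):
    try:
        return value * FORCE_TO_PN[unit]
    except KeyError:
        raise ValueError(f"undeclared force unit {unit!r}; expected one of {sorted(FORCE_TO_PN)}")


def number_density_per_A3(mass_density_g_cm3: float, molar_mass_g_mol: float) -> float:
    """Molecular number density in Å⁻³ from a mass density in g·cm⁻³."""
    return mass_density_g_cm3 / molar_mass_g_mol * AVOGADRO * 1.0e-24
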