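"""Unit conversions between user-facing and internal (CGS) unit systems.

All model mathematics runs in CGS: lengths in cm, time in s, amounts in
molecules, densities in cm^-3.  Users supply colony radii in mm, cell widths
in µm, cell densities in cells/mL (numerically identical to cells/cm^3) and
read concentrations in nM.  Every conversion lives here so no factor is
duplicated elsewhere.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # molecules per mole (exact, SI 2019)

#: molecules·cm^-3 corresponding to 1 nM: 1e-9 mol/L * AVOGADRO / 1000 cm^3/L
MOLECULES_PER_CM3_PER_NM = AVOGADRO * 1e-9 / 1000.0

MM_PER_CM = 10.0
UM_PER_CM = 1.0e4


def mm_to_cm(x_mm: float) -> float:
    return x_mm / MM_PER_CM


def cm_to_mm(x_cm: float) -> float:
    return x_cm * MM_PER_CM


def um_to_cm(x_um: float) -> float:
    return x_um / UM_PER_CM


def cm_to_um(x_cm: float) -> float:
    return x_cm * UM_PER_CM


def molecules_per_cm3_to_nM(c):
    """Convert a number density (molecules/cm^3) to nanomolar."""
    return c / MOLECULES_PER_CM3_PER_NM


def nM_to_molecules_per_cm3(c_nM):
    """Inverse of :func:`molecules_per_cm3_to_nM`; round-trips exactly."""
    return c_nM * MOLECULES_PER_CM3_PER_NM
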