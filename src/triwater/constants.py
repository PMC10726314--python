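"""Physical constants and unit conversions.

Internal unit system: lengths in nm, time in ps, charge in e, energy in
kJ/mol, temperature in K.  Electrostatic moments are reported in Debye (D)
and Debye-Angstrom (D*A, identical to the Buckingham for quadrupoles);
radial grids are exposed in Angstrom.  All conversions live here so that no
module carries its own copy of a constant.
"""

from __future__ import annotations

from types import MappingProxyType

# CODATA 2018
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K
GAS_CONSTANT = AVOGADRO * BOLTZMANN  # J/(mol K), 8.31446...
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

DEBYE = 3.33564095e-30  # C m
# 1 e*A = 1.602...e-29 C m = 4.803205 D (fixed at this printed precision)
E_ANGSTROM_TO_DEBYE = 4.803205

WATER_MOLAR_MASS = 18.0153  # g/mol

NM = 1e-9  # m
ANGSTROM = 1e-10  # m
PS = 1e-12  # s
BAR = 1e5  # Pa

CONSTANTS = MappingProxyType(
    {
        "e": ELEMENTARY_CHARGE,
        "N_A": AVOGADRO,
        "k_B": BOLTZMANN,
        "R": GAS_CONSTANT,
        "eps_0": VACUUM_PERMITTIVITY,
        "debye": DEBYE,
        "eA_to_D": E_ANGSTROM_TO_DEBYE,
    }
)
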