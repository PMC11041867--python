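"""Physical constants (CODATA 2018) and unit-conversion factors.

All unit conversions in the package route through this table so that a
single set of pinned values governs every computed quantity.
"""

import math

#: Planck constant, J s
PLANCK_H = 6.62607015e-34
#: Reduced Planck constant, J s
HBAR = 1.054571817e-34
#: Speed of light in vacuum, cm/s (wavenumber conventions use cm)
C_CM_PER_S = 2.99792458e10
#: Elementary charge, C
E_CHARGE = 1.602176634e-19
#: Vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12

#: hc in J cm — converts a wavenumber (cm^-1) to an energy (J)
HC_J_CM = PLANCK_H * C_CM_PER_S

#: One atomic unit of electric dipole moment (e * a0), C m
AU_DIPOLE_CM = 8.4783536255e-30
#: One Debye, C m  (1 D = 1e-21 / c[m/s] C m)
DEBYE_CM = 1.0e-21 / 2.99792458e8
#: Debye per atomic unit of dipole (≈ 2.5417)
DEBYE_PER_AU = AU_DIPOLE_CM / DEBYE_CM

#: Ångström in metres
ANGSTROM_M = 1.0e-10

#: 4·pi·epsilon_0, C^2 J^-1 m^-1
FOUR_PI_EPS0 = 4.0 * math.pi * EPSILON_0
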