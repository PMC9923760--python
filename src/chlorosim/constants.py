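"""Physical constants in the package's working units.

Units policy (pinned for the whole package):

* structure:      nanometres (nm)
* electrostatics: angstroms (Å) and elementary charges (e)
* energies:       wavenumbers (cm^-1)
* time:           femtoseconds (fs)
* dipoles:        Debye (D)

All prefactors below are derived once from CODATA values of e, eps0, h, c
and are unit-tested against independent hand evaluations.
"""

from __future__ import annotations

import math

# CODATA 2018 base constants (SI)
_E_CHARGE = 1.602176634e-19        # C
_EPS0 = 8.8541878128e-12           # F/m
_H_PLANCK = 6.62607015e-34         # J s
_C_LIGHT = 2.99792458e8            # m/s
_DEBYE = 3.33564095198e-30         # C m

#: speed of light in cm/fs; converts cm^-1 * fs into optical cycles.
C_CM_PER_FS = _C_LIGHT * 100.0 * 1e-15  # 2.99792458e-5

#: angular frequency per wavenumber: omega[rad/fs] = TWO_PI_C * energy[cm^-1]
TWO_PI_C = 2.0 * math.pi * C_CM_PER_FS

#: hbar expressed so that phase = H[cm^-1] * t[fs] * TWO_PI_C; kept for
#: readability where an explicit hbar is expected (cm^-1 fs).
HBAR_CM_FS = 1.0 / TWO_PI_C

# e^2/(4 pi eps0) for R in Å, energy in cm^-1:   V = COULOMB_CM_ANG * q1*q2 / R
_JOULE_PER_CM1 = _H_PLANCK * _C_LIGHT * 100.0
COULOMB_CM_ANG = (_E_CHARGE ** 2 / (4.0 * math.pi * _EPS0 * 1e-10)) / _JOULE_PER_CM1
# ~ 116140.97 cm^-1 Å e^-2

# mu^2/(4 pi eps0 R^3) for mu in Debye, R in Å, energy in cm^-1:
# J = DIPOLE_CM_ANG3 * mu_m*mu_n * kappa / R^3
DIPOLE_CM_ANG3 = (_DEBYE ** 2 / (4.0 * math.pi * _EPS0 * 1e-30)) / _JOULE_PER_CM1
# ~ 5034.12 cm^-1 Å^3 D^-2

#: monomer Qy transition energy of BChl c (methanol reference), cm^-1
OMEGA0_CM = 15390.0

#: monomer Qy transition dipole magnitude, Debye
DIPOLE_MAG_D = 5.48

NM_TO_ANG = 10.0
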