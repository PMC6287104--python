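"""Physical constants and unit helpers.

Potentials throughout the package are dimensionless (kT/e at the solver
temperature); lengths are Angstrom, charges elementary charges, energies
kcal/mol.  The two packaged constants fix all conversions:

* ``COULOMB_KCAL`` — e^2/(4 pi eps0) expressed in kcal mol^-1 A e^-2, so the
  vacuum interaction energy of two unit charges at distance r (A) is
  ``COULOMB_KCAL / r`` kcal/mol.
* ``KB_KCAL`` — Boltzmann constant in kcal mol^-1 K^-1.
"""

from __future__ import annotations

import math

COULOMB_KCAL: float = 332.0636  # kcal mol^-1 A e^-2
KB_KCAL: float = 0.0019872  # kcal mol^-1 K^-1
AVOGADRO: float = 6.02214076e23  # mol^-1


def thermal_energy_kcal(temperature: float) -> float:
    """kT in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature


def coulomb_scale_length(temperature: float) -> float:
    """Vacuum Coulomb scale length l0 = e^2/(4 pi eps0 kT) in Angstrom.

    The potential of a charge q at distance r in a medium of dielectric eps is
    ``q * l0 / (eps * r)`` in kT/e units; l0/eps is the Bjerrum length.
    """
    return COULOMB_KCAL / thermal_energy_kcal(temperature)


def bjerrum_length(temperature: float, eps: float) -> float:
    """Bjerrum length in a medium of relative dielectric ``eps`` (Angstrom)."""
    return coulomb_scale_length(temperature) / eps


def debye_kappa(ionic_strength: float, temperature: float, eps: float) -> float:
    """Inverse Debye screening length kappa (A^-1) for a univalent salt.

    kappa^2 = 8 pi l_B n with l_B the Bjerrum length and n the number density
    of salt formula units, n = N_A * I * 1e-27 A^-3 for I in mol/L.
    """
    if ionic_strength <= 0:
        return 0.0
    number_density = AVOGADRO * ionic_strength * 1e-27  # A^-3
    kappa2 = 8.0 * math.pi * bjerrum_length(temperature, eps) * number_density
    return math.sqrt(kappa2)


def debye_length(ionic_strength: float, temperature: float, eps: float) -> float:
    """Debye screening length kappa^-1 in Angstrom (inf for zero salt)."""
    kappa = debye_kappa(ionic_strength, temperature, eps)
    return math.inf if kappa == 0.0 else 1.0 / kappa
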