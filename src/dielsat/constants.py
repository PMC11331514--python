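"""Physical constants (CODATA 2018) and unit conversions.

Internal unit system: lengths in angstrom, energies in units of k_B*T,
charges in units of the elementary charge e0.  All conversions between SI
and internal units are centralised here.
"""

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: mol/L -> ions/A^3  (1 M = 6.02214e-4 ions per cubic angstrom)
MOLAR_TO_PER_A3 = AVOGADRO / 1.0e27

#: Bjerrum length prefactor e0^2/(4 pi eps0 k_B) in units of A*K:
#: l_B = BJERRUM_PREFACTOR_AK / (eps_r * T)
BJERRUM_PREFACTOR_AK = (
    ELEMENTARY_CHARGE**2 / (4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY * BOLTZMANN)
) * 1.0e10


def molar_to_density(c: float) -> float:
    """Convert a molar concentration (mol/L) to number density (ions/A^3)."""
    return c * MOLAR_TO_PER_A3


def density_to_molar(n: float) -> float:
    """Convert a number density (ions/A^3) to molar concentration (mol/L)."""
    return n / MOLAR_TO_PER_A3
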