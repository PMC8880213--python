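"""Physical constants and unit conversions.

Internal units are kcal/mol (energy), Å (length), e (charge) and K
(temperature) throughout the package.  Quantities quoted in atomic units
(Hartree, Bohr) are converted at the configuration boundary.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed constants of the internal unit system.

    Attributes
    ----------
    boltzmann_k : float
        Boltzmann constant, kcal mol^-1 K^-1.
    coulomb_k : float
        Coulomb prefactor, kcal Å mol^-1 e^-2 (e^2/Bohr expressed in
        kcal/mol and Å).
    hartree_to_kcalmol : float
        1 Hartree in kcal/mol.
    bohr_to_angstrom : float
        1 Bohr in Å.
    """

    boltzmann_k: float = 1.9872041e-3
    coulomb_k: float = 332.0637
    hartree_to_kcalmol: float = 627.5095
    bohr_to_angstrom: float = 0.529177


CONSTANTS = PhysicalConstants()

#: Default simulation temperature (K): optimal growth temperature of the
#: thermophile whose enzyme motivated the protocol.
DEFAULT_TEMPERATURE = 358.0

#: Default convergence threshold for string optimization, kcal/mol
#: (1e-10 Hartree converted).
DEFAULT_DELTA_V_TOL = 1e-10 * CONSTANTS.hartree_to_kcalmol

#: Default cap on a single image displacement during path evolution, Å
#: (1.0 Bohr converted).
DEFAULT_MAX_STEP = 1.0 * CONSTANTS.bohr_to_angstrom


def beta(temperature: float) -> float:
    """Reciprocal temperature 1/(k_B T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (CONSTANTS.boltzmann_k * temperature)
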