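"""Physical constants in the kJ/mol + nm + K unit system used throughout."""

from scipy import constants as _si

#: Boltzmann constant in kJ/mol/K (i.e. the molar gas constant / 1000).
KB = _si.k * _si.N_A / 1000.0

#: Default simulation temperature (K) for all sampling and unbiasing.
DEFAULT_TEMPERATURE = 310.0

#: Elementary charge in coulomb.
ELEMENTARY_CHARGE = _si.e

#: Planck constant in J s.
PLANCK = _si.h

#: Boltzmann constant in J/K (SI), for the Eyring prefactor.
KB_SI = _si.k


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
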