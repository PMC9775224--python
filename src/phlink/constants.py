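"""Physical constants and unit conversions used across the package.

All free energies are kept in kJ/mol internally; kcal/mol is a display
conversion only. The single source of RT ln10 lives here so the linkage
integrals, Boltzmann concentration maps and landscape energies can never
disagree on the temperature prefactor.
"""

from __future__ import annotations

import math

#: molar gas constant, kJ mol^-1 K^-1
R_KJ: float = 8.31446261815324e-3

#: Faraday constant, C mol^-1
FARADAY: float = 96485.33212331001

#: Avogadro constant, mol^-1
N_AVOGADRO: float = 6.02214076e23

#: natural log of 10
LN10: float = math.log(10.0)

#: default absolute temperature, K
DEFAULT_TEMPERATURE: float = 300.0

#: kJ per kcal
KJ_PER_KCAL: float = 4.184


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT in kJ/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ * temperature


def rt_ln10(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT ln(10) in kJ/mol — the linkage prefactor."""
    return rt(temperature) * LN10


def kj_to_kcal(x):
    """Convert kJ/mol values to kcal/mol."""
    return x / KJ_PER_KCAL
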