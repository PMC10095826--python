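"""Physical constants and unit conventions.

Internal units throughout the package: kcal/mol (energy), angstrom (length),
radian (angle), amu (mass), kelvin (temperature).  The implied time unit of
the overdamped integrator is the picosecond (friction in 1/ps).
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Coulomb conversion factor, kcal mol^-1 A e^-2 (Amber convention).
COULOMB = 332.0637141

#: Standard-state volume per molecule at 1 M, A^3.
V_STANDARD = 1660.54


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
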