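"""Physical constants and unit conventions.

All energies are in kcal/mol, charges in elementary charge units (e),
temperatures in kelvin. Lengths and the toy coordinate are dimensionless
"units"; force constants are kcal/mol/unit^2.
"""

#: Boltzmann constant / gas constant, kcal mol^-1 K^-1.
KB: float = 0.0019872

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 298.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
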