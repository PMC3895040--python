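"""Physical constants and shared defaults (molar MD units: kJ/mol, nm, ps, amu)."""

#: Molar gas constant in kJ mol^-1 K^-1; k_B T is expressed per mole throughout.
R_GAS = 0.0083145

#: Default simulation / conversion temperature in K.
DEFAULT_TEMPERATURE = 298.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy R*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature
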