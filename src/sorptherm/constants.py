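"""Physical constants and unit helpers used across the package."""

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.38e-23

#: Cross-sectional area of one sorbed water molecule, m^2.
A_WATER_MOLECULE = 1.06e-19

#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


def c_to_k(t_celsius: float) -> float:
    """Convert a temperature from degrees Celsius to kelvin."""
    return t_celsius + CELSIUS_OFFSET


def k_to_c(t_kelvin: float) -> float:
    """Convert a temperature from kelvin to degrees Celsius."""
    return t_kelvin - CELSIUS_OFFSET
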