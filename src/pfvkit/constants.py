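"""Physical constants used throughout the package (SI units)."""

FARADAY = 96485.332
"""Faraday constant, C mol^-1."""

GAS_CONSTANT = 8.314462
"""Molar gas constant, J mol^-1 K^-1."""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant, J K^-1."""

PLANCK = 6.62607e-34
"""Planck constant, J s."""

SCE_TO_SHE_VOLT = 0.2412
"""Potential of the saturated calomel electrode vs SHE at 25 degC, V."""

CELSIUS_OFFSET = 273.15
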