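"""Physical constants used throughout the package (CODATA values)."""

FARADAY = 96485.339
"""Faraday constant, C mol^-1."""

GAS_CONSTANT = 8.314472
"""Molar gas constant, J mol^-1 K^-1."""
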